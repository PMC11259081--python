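"""Array-backed production engine for large runs.

Mirrors the event semantics of :mod:`circgenome.event_engine` (the object
reference implementation) on flat numpy arrays with numba-compiled
kernels, making desk-scale scenario runs (tens of thousands of molecules,
hundreds of thousands of Monte Carlo steps) tractable.  The two engines
are cross-checked in the test suite on the model invariants (mass
conservation, null dynamics, topology rules); trajectories are not
bitwise comparable between engines because their draw orders differ, but
each engine is exactly reproducible from its seed.

Bases are encoded A=0, G=1, C=2, U=3, so the Watson-Crick complement of
code ``b`` is ``3 - b``.  Sequences are rows of fixed-width uint8 arrays
(maximum chain length :data:`MAXLEN`); random ligations that would exceed
the cap are discarded (chains this long never matter at the scales the
model runs at).

Strand states: 0 = dead slot, 1 = free strand, 2 = complex template.
Bound substrates live in the segment pool.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .model_core import BASES, Parameters, canonical_rotation

MAXLEN = 40

#: indices into the float parameter vector
P_AT, P_BB, P_EL, P_FP, P_MN, P_MNP, P_ND, P_NDE, P_NF, P_NFR, P_RL, \
    P_SP, P_TL, P_TLR, F_DA, F_LT = range(16)
#: indices into the int parameter vector
T_REP, T_NR = range(2)

_B2C = {b: i for i, b in enumerate(BASES)}
_C2B = {i: b for i, b in enumerate(BASES)}


def encode_seq(seq: str) -> np.ndarray:
    return np.array([_B2C[b] for b in seq], dtype=np.uint8)


def decode_seq(row: np.ndarray, length: int) -> str:
    return "".join(_C2B[int(c)] for c in row[:length])


def params_vectors(p: Parameters):
    pf = np.array([p.P_AT, p.P_BB, p.P_EL, p.P_FP, p.P_MN, p.P_MNP,
                   p.P_ND, p.P_NDE, p.P_NF, p.P_NFR, p.P_RL, p.P_SP,
                   p.P_TL, p.P_TLR, p.F_DA, p.F_LT], dtype=np.float64)
    pi = np.array([p.T_REP, p.T_NR], dtype=np.int64)
    return pf, pi


# ---------------------------------------------------------------------------
# State container
# ---------------------------------------------------------------------------

class FastState:
    """Flat-array system state for the compiled kernels."""

    def __init__(self, params: Parameters, rng: np.random.Generator,
                 cap_strands: int = 8192, cap_complexes: int = 4096,
                 cap_segments: int = 8192):
        N = params.N
        self.N = N
        R = N * N
        self.rng = rng
        self.step_count = 0
        self.inoculated_mass = 0
        self.initial_mass = int(params.T_NPB)
        self.prec = np.zeros(R, dtype=np.int64)
        self.nuc = np.zeros((R, 4), dtype=np.int64)
        if params.T_NPB > 0:
            self.prec += rng.multinomial(params.T_NPB, np.full(R, 1.0 / R))
        idx = np.arange(R)
        r, c = idx // N, idx % N
        self.neigh = np.stack([((r - 1) % N) * N + c, ((r + 1) % N) * N + c,
                               r * N + (c - 1) % N, r * N + (c + 1) % N],
                              axis=1).astype(np.int64)
        # strand pool
        self._alloc_strands(cap_strands)
        self._alloc_complexes(cap_complexes)
        self._alloc_segments(cap_segments)
        # scratch: per-room bucket tables filled each step by the kernel
        self.bucket_cnt = np.zeros(R * (MAXLEN + 1), dtype=np.int64)
        self.bucket_off = np.zeros(R * (MAXLEN + 1) + 1, dtype=np.int64)
        self.rep_turn = np.zeros(R, dtype=np.int64)
        self.nr_turn = np.zeros(R, dtype=np.int64)
        self.cs_rep = encode_seq(params.CS_REP)
        self.cs_nr = encode_seq(params.CS_NR)
        # species-scoped F_LT rules (empty by default)
        self.clear_flt_rules()

    # -- pools -------------------------------------------------------------

    def _alloc_strands(self, cap):
        self.s_seq = np.zeros((cap, MAXLEN), dtype=np.uint8)
        self.s_len = np.zeros(cap, dtype=np.int64)
        self.s_room = np.zeros(cap, dtype=np.int64)
        self.s_circ = np.zeros(cap, dtype=np.uint8)
        self.s_state = np.zeros(cap, dtype=np.uint8)
        self.s_hi = 0

    def _alloc_complexes(self, cap):
        self.c_tpl = np.full(cap, -1, dtype=np.int64)
        self.c_alive = np.zeros(cap, dtype=np.uint8)
        self.c_first = np.full(cap, -1, dtype=np.int64)
        self.c_nseg = np.zeros(cap, dtype=np.int64)
        self.c_npair = np.zeros(cap, dtype=np.int64)
        self.c_mask = np.zeros(cap, dtype=np.int64)
        self.c_hi = 0

    def _alloc_segments(self, cap):
        self.g_seq = np.zeros((cap, MAXLEN), dtype=np.uint8)
        self.g_len = np.zeros(cap, dtype=np.int64)
        self.g_start = np.zeros(cap, dtype=np.int64)
        self.g_owner = np.full(cap, -1, dtype=np.int64)
        self.g_next = np.full(cap, -1, dtype=np.int64)
        self.g_alive = np.zeros(cap, dtype=np.uint8)
        self.g_hi = 0

    def _grow(self, which: str) -> None:
        if which == "s":
            old = (self.s_seq, self.s_len, self.s_room, self.s_circ,
                   self.s_state)
            n = self.s_seq.shape[0]
            self._alloc_strands(2 * n)
            self.s_seq[:n] = old[0]
            self.s_len[:n] = old[1]
            self.s_room[:n] = old[2]
            self.s_circ[:n] = old[3]
            self.s_state[:n] = old[4]
            self.s_hi = n
        elif which == "c":
            old = (self.c_tpl, self.c_alive, self.c_first, self.c_nseg,
                   self.c_npair, self.c_mask)
            n = self.c_tpl.shape[0]
            self._alloc_complexes(2 * n)
            self.c_tpl[:n] = old[0]
            self.c_alive[:n] = old[1]
            self.c_first[:n] = old[2]
            self.c_nseg[:n] = old[3]
            self.c_npair[:n] = old[4]
            self.c_mask[:n] = old[5]
            self.c_hi = n
        else:
            old = (self.g_seq, self.g_len, self.g_start, self.g_owner,
                   self.g_next, self.g_alive)
            n = self.g_seq.shape[0]
            self._alloc_segments(2 * n)
            self.g_seq[:n] = old[0]
            self.g_len[:n] = old[1]
            self.g_start[:n] = old[2]
            self.g_owner[:n] = old[3]
            self.g_next[:n] = old[4]
            self.g_alive[:n] = old[5]
            self.g_hi = n

    def ensure_headroom(self) -> None:
        """Keep each pool able to absorb a step's worth of new objects.

        Dead low-index slots are compacted away lazily: the kernels
        allocate past the high-water mark, and compaction rewrites the
        pools once the high-water mark nears capacity.
        """
        if self.s_hi + 4096 > self.s_seq.shape[0]:
            if int((self.s_state[:self.s_hi] != 0).sum()) \
                    < self.s_seq.shape[0] // 2:
                self._compact()
            else:
                self._grow("s")
        if self.c_hi + 2048 > self.c_tpl.shape[0]:
            if int(self.c_alive[:self.c_hi].sum()) < self.c_tpl.shape[0] // 2:
                self._compact()
            else:
                self._grow("c")
        if self.g_hi + 4096 > self.g_seq.shape[0]:
            if int(self.g_alive[:self.g_hi].sum()) < self.g_seq.shape[0] // 2:
                self._compact()
            else:
                self._grow("g")

    def _compact(self) -> None:
        """Repack live strands/complexes/segments to the front of the pools."""
        smap = np.full(self.s_hi, -1, dtype=np.int64)
        live_s = np.nonzero(self.s_state[:self.s_hi] != 0)[0]
        smap[live_s] = np.arange(live_s.size)
        cmap = np.full(self.c_hi, -1, dtype=np.int64)
        live_c = np.nonzero(self.c_alive[:self.c_hi] != 0)[0]
        cmap[live_c] = np.arange(live_c.size)
        gmap = np.full(self.g_hi, -1, dtype=np.int64)
        live_g = np.nonzero(self.g_alive[:self.g_hi] != 0)[0]
        gmap[live_g] = np.arange(live_g.size)

        self.s_seq[:live_s.size] = self.s_seq[live_s]
        self.s_len[:live_s.size] = self.s_len[live_s]
        self.s_room[:live_s.size] = self.s_room[live_s]
        self.s_circ[:live_s.size] = self.s_circ[live_s]
        self.s_state[:live_s.size] = self.s_state[live_s]
        self.s_state[live_s.size:self.s_hi] = 0
        self.s_hi = int(live_s.size)

        self.c_tpl[:live_c.size] = smap[self.c_tpl[live_c]]
        first = self.c_first[live_c]
        self.c_first[:live_c.size] = np.where(first >= 0, gmap[first], -1)
        self.c_alive[:live_c.size] = 1
        self.c_nseg[:live_c.size] = self.c_nseg[live_c]
        self.c_npair[:live_c.size] = self.c_npair[live_c]
        self.c_mask[:live_c.size] = self.c_mask[live_c]
        self.c_alive[live_c.size:self.c_hi] = 0
        self.c_hi = int(live_c.size)

        self.g_seq[:live_g.size] = self.g_seq[live_g]
        self.g_len[:live_g.size] = self.g_len[live_g]
        self.g_start[:live_g.size] = self.g_start[live_g]
        self.g_owner[:live_g.size] = cmap[self.g_owner[live_g]]
        nxt = self.g_next[live_g]
        self.g_next[:live_g.size] = np.where(nxt >= 0, gmap[nxt], -1)
        self.g_alive[:live_g.size] = 1
        self.g_alive[live_g.size:self.g_hi] = 0
        self.g_hi = int(live_g.size)

    # -- construction helpers ----------------------------------------------

    def add_strand(self, seq: str, circular: bool, room: int) -> int:
        """Insert a free strand (canonicalizing circular sequences)."""
        if len(seq) > MAXLEN:
            raise ValueError(f"sequence longer than MAXLEN={MAXLEN}")
        if circular:
            seq = canonical_rotation(seq)
        while self.s_hi >= self.s_seq.shape[0]:
            self._grow("s")
        i = self.s_hi
        self.s_hi += 1
        codes = encode_seq(seq)
        self.s_seq[i, :len(seq)] = codes
        self.s_len[i] = len(seq)
        self.s_room[i] = room
        self.s_circ[i] = 1 if circular else 0
        self.s_state[i] = 1
        return i

    # -- species-scoped F_LT rules ------------------------------------------

    def clear_flt_rules(self) -> None:
        self.rule_val = np.zeros(0, dtype=np.float64)
        self.rule_topo = np.zeros(0, dtype=np.int8)
        self.mot_seq = np.zeros((0, MAXLEN), dtype=np.uint8)
        self.mot_len = np.zeros(0, dtype=np.int64)
        self.mot_rule = np.zeros(0, dtype=np.int64)

    def add_flt_rule(self, scope, value: float) -> None:
        """Scoped F_LT rule; scope is a SpeciesScope (contains_any only)."""
        if scope.not_contains:
            raise ValueError("not_contains scopes are not supported by the "
                             "array engine")
        topo = {-1: -1, "linear": 0, "circular": 1}[
            scope.topology if scope.topology is not None else -1]
        r = self.rule_val.size
        self.rule_val = np.append(self.rule_val, np.float64(value))
        self.rule_topo = np.append(self.rule_topo, np.int8(topo))
        for m in scope.contains_any:
            row = np.zeros((1, MAXLEN), dtype=np.uint8)
            row[0, :len(m)] = encode_seq(m)
            self.mot_seq = np.vstack([self.mot_seq, row])
            self.mot_len = np.append(self.mot_len, np.int64(len(m)))
            self.mot_rule = np.append(self.mot_rule, np.int64(r))

    # -- observation --------------------------------------------------------

    @property
    def step(self) -> int:
        """Completed Monte Carlo steps (alias of ``step_count``)."""
        return self.step_count

    def target_mass(self) -> int:
        return self.initial_mass + self.inoculated_mass

    def total_mass(self) -> int:
        m = int(self.prec.sum()) + int(self.nuc.sum())
        m += int(self.s_len[:self.s_hi][self.s_state[:self.s_hi] != 0].sum())
        m += int(self.g_len[:self.g_hi][self.g_alive[:self.g_hi] != 0].sum())
        return m

    def iter_strands(self):
        """Yield (sequence, circular, room, engaged) over every strand."""
        for i in range(self.s_hi):
            st = self.s_state[i]
            if st == 0:
                continue
            yield (decode_seq(self.s_seq[i], int(self.s_len[i])),
                   bool(self.s_circ[i]), int(self.s_room[i]), st == 2)
        for j in range(self.g_hi):
            if self.g_alive[j]:
                cx = int(self.g_owner[j])
                room = int(self.s_room[self.c_tpl[cx]])
                yield (decode_seq(self.g_seq[j], int(self.g_len[j])),
                       False, room, True)


# ---------------------------------------------------------------------------
# Compiled primitives
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _binom(gen, n, p):
    """Binomial(n, p) by geometric gap skipping; O(successes + 1) draws."""
    if p <= 0.0 or n <= 0:
        return 0
    if p >= 1.0:
        return n
    l1p = math.log1p(-p)
    k = 0
    i = -1
    while True:
        u = gen.random()
        i += int(math.log(u) / l1p) + 1
        if i >= n:
            return k
        k += 1


@njit(cache=True)
def _contains(row, L, circ, mot, mlen):
    """Motif containment; rotation-invariant when ``circ`` is nonzero."""
    if mlen > L or mlen < 1:
        return False
    lim = L if circ else L - mlen + 1
    for s in range(lim):
        ok = True
        for k in range(mlen):
            idx = s + k
            if idx >= L:
                idx -= L
            if row[idx] != mot[k]:
                ok = False
                break
        if ok:
            return True
    return False


@njit(cache=True)
def _ribo_kind(row, L, cs_rep, cs_nr):
    """1 = functional REP, 2 = functional NR, 3 = both (linear chains)."""
    kind = 0
    nr_ = cs_rep.size
    if L >= nr_ and 2 * L < 3 * nr_ and _contains(row, L, 0, cs_rep, nr_):
        kind |= 1
    nn = cs_nr.size
    if L >= nn and 2 * L < 3 * nn and _contains(row, L, 0, cs_nr, nn):
        kind |= 2
    return kind


@njit(cache=True)
def _eff_flt(row, L, circ, base, rule_val, rule_topo, mot_seq, mot_len,
             mot_rule):
    """Effective linear-template factor under scoped rules (last wins)."""
    nrules = rule_val.size
    if nrules == 0:
        return base
    for r in range(nrules - 1, -1, -1):
        if rule_topo[r] == 0 and circ:
            continue
        if rule_topo[r] == 1 and not circ:
            continue
        has_m = False
        hit = False
        for m in range(mot_rule.size):
            if mot_rule[m] == r:
                has_m = True
                if _contains(row, L, circ, mot_seq[m], mot_len[m]):
                    hit = True
                    break
        if hit or not has_m:
            return rule_val[r]
    return base


@njit(cache=True)
def _canonical_into(src, L, dst):
    """Write the lexicographically smallest rotation of src[:L] into dst."""
    best = 0
    for s in range(1, L):
        for k in range(L):
            a = src[(s + k) % L]
            b = src[(best + k) % L]
            if a < b:
                best = s
                break
            if a > b:
                break
    for k in range(L):
        dst[k] = src[(best + k) % L]


@njit(cache=True, inline="always")
def _recompute_mask(cx, c_mask, c_first, g_next, g_start, g_len, L, circ):
    mask = 0
    j = c_first[cx]
    while j >= 0:
        if circ:
            for k in range(g_len[j]):
                mask |= 1 << ((g_start[j] + k) % L)
        else:
            mask |= ((1 << g_len[j]) - 1) << g_start[j]
        j = g_next[j]
    c_mask[cx] = mask


# ---------------------------------------------------------------------------
# In-kernel object helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _release_seq(room, row, L, prec, nuc, s_seq, s_len, s_room, s_circ,
                 s_state, ctr):
    """Free a chain: 1-mers rejoin the nucleotide pool, longer become
    free strands (slot allocated past the high-water mark)."""
    if L == 1:
        nuc[room, row[0]] += 1
    else:
        i = ctr[0]
        ctr[0] = i + 1
        for k in range(L):
            s_seq[i, k] = row[k]
        s_len[i] = L
        s_room[i] = room
        s_circ[i] = 0
        s_state[i] = 1


@njit(cache=True, inline="always")
def _dissolve_if_empty(cx, c_alive, c_nseg, c_tpl, prec, nuc, s_seq, s_len,
                       s_room, s_circ, s_state):
    """Dissolve a segment-less complex; its template becomes free again."""
    if c_nseg[cx] != 0:
        return False
    c_alive[cx] = 0
    t = c_tpl[cx]
    if s_len[t] == 1:
        nuc[s_room[t], s_seq[t, 0]] += 1
        s_state[t] = 0
    else:
        s_state[t] = 1
    return True


@njit(cache=True, inline="always")
def _seg_bits(start, length, L, circ):
    if circ and start + length > L:
        m = 0
        for k in range(length):
            m |= 1 << ((start + k) % L)
        return m
    return ((1 << length) - 1) << (start % L if circ else start)


@njit(cache=True, inline="always")
def _add_segment(cx, start, src, slen, c_first, c_nseg, c_npair, c_mask,
                 g_seq, g_len, g_start, g_owner, g_next, g_alive, ctr, L,
                 circ):
    j = ctr[2]
    ctr[2] = j + 1
    for k in range(slen):
        g_seq[j, k] = src[k]
    g_len[j] = slen
    g_start[j] = start % L if circ else start
    g_owner[j] = cx
    g_next[j] = c_first[cx]
    g_alive[j] = 1
    c_first[cx] = j
    c_nseg[cx] += 1
    c_npair[cx] += slen
    c_mask[cx] |= _seg_bits(start, slen, L, circ)
    return j


@njit(cache=True)
def _unlink_segment(cx, j, c_first, c_nseg, c_npair, c_mask, g_next, g_len,
                    g_start, g_alive, L, circ):
    prev = -1
    cur = c_first[cx]
    while cur != j:
        prev = cur
        cur = g_next[cur]
    if prev < 0:
        c_first[cx] = g_next[j]
    else:
        g_next[prev] = g_next[j]
    g_alive[j] = 0
    c_nseg[cx] -= 1
    c_npair[cx] -= g_len[j]
    c_mask[cx] &= ~_seg_bits(g_start[j], g_len[j], L, circ)


# ---------------------------------------------------------------------------
# Attraction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bind_at_pos_k(gen, tpl, cx, pos, pf, prec, nuc,
                   s_seq, s_len, s_room, s_circ, s_state,
                   c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                   g_seq, g_len, g_start, g_owner, g_next, g_alive,
                   bucket_cnt, bucket_off, members, ctr, counts):
    """Resolve one successful attraction at empty template position pos.

    ``cx`` is the complex index, or -1 when the template ``tpl`` is still
    a free strand (fully empty).  Returns the complex index on a bind
    (creating the complex if needed), or -1 on failure.
    """
    L = s_len[tpl]
    circ = s_circ[tpl] != 0
    room = s_room[tpl]
    mask = c_mask[cx] if cx >= 0 else 0

    # empty run around pos
    if mask == 0:
        rs = 0
        rg = L
        off = pos
    else:
        lcount = 0
        q = pos
        while lcount < L:
            qq = (q - 1) % L if circ else q - 1
            if qq < 0 or (mask >> qq) & 1:
                break
            q = qq
            lcount += 1
        rcount = 0
        q = pos
        while rcount < L:
            qq = (q + 1) % L if circ else q + 1
            if (not circ) and qq >= L:
                break
            if (mask >> (qq % L)) & 1:
                break
            q = qq % L
            rcount += 1
        rs = pos - lcount
        rg = lcount + 1 + rcount
        off = lcount

    counts[8] += 1
    n_nuc = nuc[room, 0] + nuc[room, 1] + nuc[room, 2] + nuc[room, 3]
    base_key = room * (MAXLEN + 1)
    oligo_total = 0
    hi_l = rg if rg < MAXLEN else MAXLEN
    for l in range(2, hi_l + 1):
        oligo_total += bucket_cnt[base_key + l]
    total = n_nuc + oligo_total
    if total <= 0:
        return -1
    pick = int(gen.random() * total)

    if pick < n_nuc:
        ideal = 3 - s_seq[tpl, pos]
        base = ideal
        if pf[P_FP] > 0.0 and gen.random() < pf[P_FP]:
            alt = int(gen.random() * 3.0)
            base = alt if alt < ideal else alt + 1
        if nuc[room, base] == 0:
            return -1
        nuc[room, base] -= 1
        if cx < 0:
            cx = ctr[1]
            ctr[1] = cx + 1
            c_tpl[cx] = tpl
            c_alive[cx] = 1
            c_first[cx] = -1
            c_nseg[cx] = 0
            c_npair[cx] = 0
            c_mask[cx] = 0
            s_state[tpl] = 2
        one = np.empty(1, dtype=np.uint8)
        one[0] = base
        _add_segment(cx, pos, one, 1, c_first, c_nseg, c_npair, c_mask,
                     g_seq, g_len, g_start, g_owner, g_next, g_alive, ctr,
                     L, circ)
        counts[0] += 1
        return cx

    # oligomer substrate
    x = pick - n_nuc
    chosen_l = -1
    for l in range(2, hi_l + 1):
        cnt = bucket_cnt[base_key + l]
        if x < cnt:
            chosen_l = l
            break
        x -= cnt
    if chosen_l < 0:
        return -1
    sub = -1
    cnt2 = 0
    blo = bucket_off[base_key + chosen_l]
    bhi = bucket_off[base_key + chosen_l + 1]
    for b in range(blo, bhi):
        s2 = members[b]
        if s_state[s2] == 1 and s_circ[s2] == 0 and s2 != tpl:
            if cnt2 == x:
                sub = s2
                break
            cnt2 += 1
    if sub < 0:
        return -1  # count included the template itself
    l = chosen_l
    if circ and rg == L and mask == 0:
        lo = off - l + 1
        hi = off
    else:
        lo = off - l + 1
        if lo < 0:
            lo = 0
        hi = rg - l
        if off < hi:
            hi = off
        if hi < lo:
            return -1
    start_off = lo if hi == lo else lo + int(gen.random() * (hi - lo + 1))
    start = rs + start_off
    if circ:
        start %= L
    # false pairing as per-residue tolerance, reject on first failed draw
    for k in range(l):
        tp = (start + l - 1 - k) % L if circ else start + l - 1 - k
        if s_seq[sub, k] != 3 - s_seq[tpl, tp]:
            if pf[P_FP] <= 0.0 or gen.random() >= pf[P_FP]:
                return -1
    s_state[sub] = 0
    bucket_cnt[base_key + chosen_l] -= 1
    if cx < 0:
        cx = ctr[1]
        ctr[1] = cx + 1
        c_tpl[cx] = tpl
        c_alive[cx] = 1
        c_first[cx] = -1
        c_nseg[cx] = 0
        c_npair[cx] = 0
        c_mask[cx] = 0
        s_state[tpl] = 2
    _add_segment(cx, start, s_seq[sub], l, c_first, c_nseg, c_npair, c_mask,
                 g_seq, g_len, g_start, g_owner, g_next, g_alive, ctr, L,
                 circ)
    counts[0] += 1
    return cx


@njit(cache=True, inline="always")
def _is_flank_k(mask, pos, L, circ):
    if mask == 0:
        return False
    if circ:
        return ((mask >> ((pos - 1) % L)) & 1) | \
            ((mask >> ((pos + 1) % L)) & 1) != 0
    if pos > 0 and (mask >> (pos - 1)) & 1:
        return True
    return pos + 1 < L and (mask >> (pos + 1)) & 1 != 0


@njit(cache=True)
def _complex_attempts_k(gen, cx, k, inv_fda, pf, prec, nuc,
                        s_seq, s_len, s_room, s_circ, s_state,
                        c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                        g_seq, g_len, g_start, g_owner, g_next, g_alive,
                        bucket_cnt, bucket_off, members, ctr, counts):
    """``k`` majorant-rate site attempts on a live complex (cascade)."""
    tpl = c_tpl[cx]
    L = s_len[tpl]
    circ = s_circ[tpl] != 0
    for _ in range(k):
        E = L - c_npair[cx]
        if E <= 0:
            break
        mask = c_mask[cx]
        # walk to the e-th empty position
        e = int(gen.random() * E)
        pos = 0
        while pos < L - 1:
            if not (mask >> pos) & 1:
                if e == 0:
                    break
                e -= 1
            pos += 1
        if not _is_flank_k(mask, pos, L, circ) and gen.random() >= inv_fda:
            continue
        _bind_at_pos_k(gen, tpl, cx, pos, pf, prec, nuc,
                       s_seq, s_len, s_room, s_circ, s_state,
                       c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                       g_seq, g_len, g_start, g_owner, g_next, g_alive,
                       bucket_cnt, bucket_off, members, ctr, counts)


# ---------------------------------------------------------------------------
# Template-directed ligation
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _ligate_once_k(gen, rep_turn, room, pf):
    if rep_turn[room] > 0:
        rep_turn[room] -= 1
        p = pf[P_TLR]
    else:
        p = pf[P_TL]
    return p > 0.0 and gen.random() < p


@njit(cache=True)
def _ligate_complex_k(gen, cx, pf, rep_turn, prec, nuc,
                      s_seq, s_len, s_room, s_circ, s_state,
                      c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                      g_seq, g_len, g_start, g_owner, g_next, g_alive,
                      ctr, counts, scratch):
    """Ligation attempts at all junctions of one complex, then closure."""
    tpl = c_tpl[cx]
    L = s_len[tpl]
    circ = s_circ[tpl] != 0
    room = s_room[tpl]

    if c_nseg[cx] > 1:
        # gather and insertion-sort segment ids by start
        nseg = c_nseg[cx]
        ids = np.empty(nseg, dtype=np.int64)
        j = c_first[cx]
        for a in range(nseg):
            ids[a] = j
            j = g_next[j]
        for a in range(1, nseg):
            v = ids[a]
            b = a - 1
            while b >= 0 and g_start[ids[b]] > g_start[v]:
                ids[b + 1] = ids[b]
                b -= 1
            ids[b + 1] = v

        cur = ids[0]
        kept_first = cur
        for a in range(1, nseg):
            nxt = ids[a]
            cur_end = g_start[cur] + g_len[cur]
            if circ:
                cur_end %= L
            if cur_end == g_start[nxt] \
                    and _ligate_once_k(gen, rep_turn, room, pf):
                # merged substrate = high.seq + low.seq (antiparallel)
                lh = g_len[nxt]
                ll = g_len[cur]
                for k in range(lh):
                    scratch[k] = g_seq[nxt, k]
                for k in range(ll):
                    scratch[lh + k] = g_seq[cur, k]
                for k in range(lh + ll):
                    g_seq[cur, k] = scratch[k]
                g_len[cur] = lh + ll
                # unlink nxt
                _unlink_segment(cx, nxt, c_first, c_nseg, c_npair, c_mask,
                                g_next, g_len, g_start, g_alive, L, circ)
                # the merged residues are still paired: restore bookkeeping
                c_npair[cx] += lh
                c_mask[cx] |= _seg_bits(g_start[cur], g_len[cur], L, circ)
                counts[2] += 1
            else:
                cur = nxt
        # wrap junction on a circular template
        if circ and c_nseg[cx] > 1:
            nseg2 = c_nseg[cx]
            j = c_first[cx]
            first = -1
            last = -1
            for a in range(nseg2):
                if first < 0 or g_start[j] < g_start[first]:
                    first = j
                if last < 0 or g_start[j] > g_start[last]:
                    last = j
                j = g_next[j]
            if (g_start[last] + g_len[last]) % L == g_start[first] \
                    and _ligate_once_k(gen, rep_turn, room, pf):
                lh = g_len[first]
                ll = g_len[last]
                for k in range(lh):
                    scratch[k] = g_seq[first, k]
                for k in range(ll):
                    scratch[lh + k] = g_seq[last, k]
                for k in range(lh + ll):
                    g_seq[last, k] = scratch[k]
                g_len[last] = lh + ll
                _unlink_segment(cx, first, c_first, c_nseg, c_npair, c_mask,
                                g_next, g_len, g_start, g_alive, L, circ)
                c_npair[cx] += lh
                c_mask[cx] |= _seg_bits(g_start[last], g_len[last], L, circ)
                counts[2] += 1

    # ring closure of a full-cover complement on a circular template
    if circ and c_nseg[cx] == 1 and c_npair[cx] == L and L >= 3:
        if _ligate_once_k(gen, rep_turn, room, pf):
            j = c_first[cx]
            i = ctr[0]
            ctr[0] = i + 1
            _canonical_into(g_seq[j], L, s_seq[i])
            s_len[i] = L
            s_room[i] = room
            s_circ[i] = 1
            s_state[i] = 1
            g_alive[j] = 0
            c_first[cx] = -1
            c_nseg[cx] = 0
            c_npair[cx] = 0
            c_mask[cx] = 0
            _dissolve_if_empty(cx, c_alive, c_nseg, c_tpl, prec, nuc, s_seq,
                               s_len, s_room, s_circ, s_state)
            counts[3] += 1


# ---------------------------------------------------------------------------
# Breaking and decay
# ---------------------------------------------------------------------------

@njit(cache=True)
def _break_free_k(gen, i, bond, prec, nuc, s_seq, s_len, s_room, s_circ,
                  s_state, ctr, scratch):
    """Break free strand ``i`` at ``bond`` (between bond and bond+1)."""
    L = s_len[i]
    if s_circ[i]:
        cut = (bond + 1) % L
        for k in range(L):
            scratch[k] = s_seq[i, (cut + k) % L]
        for k in range(L):
            s_seq[i, k] = scratch[k]
        s_circ[i] = 0
        return
    room = s_room[i]
    s_state[i] = 0
    _release_seq(room, s_seq[i], bond + 1, prec, nuc, s_seq, s_len, s_room,
                 s_circ, s_state, ctr)
    _release_seq(room, s_seq[i, bond + 1:], L - bond - 1, prec, nuc, s_seq,
                 s_len, s_room, s_circ, s_state, ctr)


@njit(cache=True)
def _break_complex_k(gen, cx, bond, double, prec, nuc,
                     s_seq, s_len, s_room, s_circ, s_state,
                     c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                     g_seq, g_len, g_start, g_owner, g_next, g_alive,
                     ctr, scratch):
    """Break the template of a complex at ``bond`` (both chains if double)."""
    tpl = c_tpl[cx]
    L = s_len[tpl]
    circ = s_circ[tpl] != 0
    if double:
        # split the spanning segment at its parallel bond
        j = c_first[cx]
        while j >= 0:
            o = (bond - g_start[j]) % L if circ else bond - g_start[j]
            if 0 <= o < g_len[j] - 1:
                n = g_len[j]
                cut = n - 1 - o   # seq[:cut] high side, seq[cut:] low side
                hstart = (bond + 1) % L if circ else bond + 1
                _add_segment(cx, hstart, g_seq[j], cut, c_first, c_nseg,
                             c_npair, c_mask, g_seq, g_len, g_start,
                             g_owner, g_next, g_alive, ctr, L, circ)
                # shrink j to the low side (residues cut..n-1)
                c_npair[cx] -= cut
                c_mask[cx] &= ~_seg_bits(g_start[j], g_len[j], L, circ)
                for k in range(n - cut):
                    g_seq[j, k] = g_seq[j, cut + k]
                g_len[j] = n - cut
                c_mask[cx] |= _seg_bits(g_start[j], g_len[j], L, circ)
                break
            j = g_next[j]
    if circ:
        # open the ring at the bond; remap segment starts
        cut = (bond + 1) % L
        for k in range(L):
            scratch[k] = s_seq[tpl, (cut + k) % L]
        for k in range(L):
            s_seq[tpl, k] = scratch[k]
        s_circ[tpl] = 0
        j = c_first[cx]
        while j >= 0:
            g_start[j] = (g_start[j] - cut) % L
            j = g_next[j]
        _recompute_mask(cx, c_mask, c_first, g_next, g_start, g_len, L, 0)
        _dissolve_if_empty(cx, c_alive, c_nseg, c_tpl, prec, nuc, s_seq,
                           s_len, s_room, s_circ, s_state)
        return
    # linear template: partition into [0, bond] and [bond+1, L)
    room = s_room[tpl]
    left_n = bond + 1
    right_n = L - bond - 1
    c_alive[cx] = 0
    s_state[tpl] = 0
    left_first = -1
    right_first = -1
    j = c_first[cx]
    while j >= 0:
        nxt = g_next[j]
        if g_start[j] + g_len[j] - 1 <= bond:
            g_next[j] = left_first
            left_first = j
        else:
            g_start[j] -= left_n
            g_next[j] = right_first
            right_first = j
        j = nxt
    for side in range(2):
        first = left_first if side == 0 else right_first
        n = left_n if side == 0 else right_n
        srcoff = 0 if side == 0 else left_n
        if n == 0:
            continue
        if first < 0:
            _release_seq(room, s_seq[tpl, srcoff:], n, prec, nuc, s_seq,
                         s_len, s_room, s_circ, s_state, ctr)
            continue
        nt = ctr[0]
        ctr[0] = nt + 1
        for k in range(n):
            s_seq[nt, k] = s_seq[tpl, srcoff + k]
        s_len[nt] = n
        s_room[nt] = room
        s_circ[nt] = 0
        s_state[nt] = 2
        nc = ctr[1]
        ctr[1] = nc + 1
        c_tpl[nc] = nt
        c_alive[nc] = 1
        c_first[nc] = first
        nseg = 0
        npair = 0
        j = first
        while j >= 0:
            g_owner[j] = nc
            nseg += 1
            npair += g_len[j]
            j = g_next[j]
        c_nseg[nc] = nseg
        c_npair[nc] = npair
        _recompute_mask(nc, c_mask, c_first, g_next, g_start, g_len, n, 0)


@njit(cache=True)
def _decay_template_end_k(cx, end3, prec, nuc,
                          s_seq, s_len, s_room, s_circ, s_state,
                          c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                          g_seq, g_len, g_start, g_owner, g_next, g_alive):
    """Terminal template residue decays (with blunt-paired partner)."""
    tpl = c_tpl[cx]
    L = s_len[tpl]
    pos = L - 1 if end3 else 0
    covering = -1
    j = c_first[cx]
    while j >= 0:
        if g_start[j] <= pos < g_start[j] + g_len[j]:
            covering = j
            break
        j = g_next[j]
    released = 1
    if covering >= 0:
        n = g_len[covering]
        if pos == g_start[covering] + n - 1:
            # drop the substrate 5' residue (seq[0])
            for k in range(n - 1):
                g_seq[covering, k] = g_seq[covering, k + 1]
        # else: drop the substrate 3' residue (seq[n-1]); start shifts up
        c_npair[cx] -= 1
        if pos == g_start[covering]:
            g_start[covering] += 1
        g_len[covering] = n - 1
        if g_len[covering] == 0:
            _unlink_segment(cx, covering, c_first, c_nseg, c_npair, c_mask,
                            g_next, g_len, g_start, g_alive, L, 0)
            c_npair[cx] += 0  # unlink already adjusted counts for len 0
        released = 2
    # remove the template residue
    if not end3:
        for k in range(L - 1):
            s_seq[tpl, k] = s_seq[tpl, k + 1]
        j = c_first[cx]
        while j >= 0:
            g_start[j] -= 1
            j = g_next[j]
    s_len[tpl] = L - 1
    _recompute_mask(cx, c_mask, c_first, g_next, g_start, g_len, L - 1, 0)
    prec[s_room[tpl]] += released
    if s_len[tpl] == 0:
        c_alive[cx] = 0
        s_state[tpl] = 0
    else:
        _dissolve_if_empty(cx, c_alive, c_nseg, c_tpl, prec, nuc, s_seq,
                           s_len, s_room, s_circ, s_state)


# ---------------------------------------------------------------------------
# The step kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step_kernel(gen, pf, pi, prec, nuc, neigh,
                 s_seq, s_len, s_room, s_circ, s_state,
                 c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                 g_seq, g_len, g_start, g_owner, g_next, g_alive,
                 bucket_cnt, bucket_off, rep_turn, nr_turn,
                 cs_rep, cs_nr, rule_val, rule_topo, mot_seq, mot_len,
                 mot_rule, sep_pow, inv_sqrt, ctr, counts,
                 phase_limit=99):
    R = prec.shape[0]
    ML1 = MAXLEN + 1
    s_hi0 = ctr[0]
    c_hi0 = ctr[1]
    scratch = np.empty(MAXLEN, dtype=np.uint8)

    # ---- gather: buckets, room strand counts, ribozyme turnovers ---------
    for k in range(R * ML1):
        bucket_cnt[k] = 0
    rep_turn[:] = 0
    nr_turn[:] = 0
    room_cnt = np.zeros(R, dtype=np.int64)
    n_lin = 0
    for i in range(s_hi0):
        if s_state[i] != 1:
            continue
        room = s_room[i]
        if s_circ[i] == 0:
            room_cnt[room] += 1
            bucket_cnt[room * ML1 + s_len[i]] += 1
            n_lin += 1
            kind = _ribo_kind(s_seq[i], s_len[i], cs_rep, cs_nr)
            if kind & 1:
                rep_turn[room] += pi[T_REP]
            if kind & 2:
                nr_turn[room] += pi[T_NR]
    for cx in range(c_hi0):
        if not c_alive[cx]:
            continue
        tpl = c_tpl[cx]
        room = s_room[tpl]
        if s_circ[tpl] == 0:
            kind = _ribo_kind(s_seq[tpl], s_len[tpl], cs_rep, cs_nr)
            if kind & 1:
                rep_turn[room] += pi[T_REP]
            if kind & 2:
                nr_turn[room] += pi[T_NR]
        j = c_first[cx]
        while j >= 0:
            kind = _ribo_kind(g_seq[j], g_len[j], cs_rep, cs_nr)
            if kind & 1:
                rep_turn[room] += pi[T_REP]
            if kind & 2:
                nr_turn[room] += pi[T_NR]
            j = g_next[j]
    # prefix sums and member table
    bucket_off[0] = 0
    for k in range(R * ML1):
        bucket_off[k + 1] = bucket_off[k] + bucket_cnt[k]
    members = np.empty(max(n_lin, 1), dtype=np.int64)
    fill = bucket_off[:R * ML1].copy()
    for i in range(s_hi0):
        if s_state[i] == 1 and s_circ[i] == 0:
            key = s_room[i] * ML1 + s_len[i]
            members[fill[key]] = i
            fill[key] += 1

    if phase_limit <= 0:
        return
    # ---- 1+2. nucleotide formation and decay -----------------------------
    for room in range(R):
        reserved = 0
        t = nr_turn[room]
        if t > 0 and pf[P_NFR] > 0.0:
            avail = prec[room]
            att = t if t < avail else avail
            succ = _binom(gen, att, pf[P_NFR])
            prec[room] -= succ
            for _ in range(succ):
                nuc[room, int(gen.random() * 4.0)] += 1
            reserved = att - succ
        if pf[P_NF] > 0.0:
            pool = prec[room] - reserved
            k = _binom(gen, pool, pf[P_NF])
            prec[room] -= k
            for _ in range(k):
                nuc[room, int(gen.random() * 4.0)] += 1
        if pf[P_ND] > 0.0:
            for b in range(4):
                d = _binom(gen, nuc[room, b], pf[P_ND])
                nuc[room, b] -= d
                prec[room] += d

    if phase_limit <= 2:
        return
    # ---- 3. random intermolecular ligation --------------------------------
    if pf[P_RL] > 0.0:
        total = 0
        for room in range(R):
            total += nuc[room, 0] + nuc[room, 1] + nuc[room, 2] \
                + nuc[room, 3] + room_cnt[room]
        k = _binom(gen, total, pf[P_RL])
        for _ in range(k):
            x = int(gen.random() * total)
            room = -1
            for r2 in range(R):
                c = nuc[r2, 0] + nuc[r2, 1] + nuc[r2, 2] + nuc[r2, 3] \
                    + room_cnt[r2]
                if x < c:
                    room = r2
                    break
                x -= c
            if room < 0:
                continue
            _random_ligation_k(gen, room, prec, nuc, s_seq, s_len, s_room,
                               s_circ, s_state, bucket_cnt, bucket_off,
                               members, ctr, counts)

    if phase_limit <= 3:
        return
    # ---- 4. circularization ----------------------------------------------
    if pf[P_EL] > 0.0:
        for i in range(ctr[0]):
            if s_state[i] == 1 and s_circ[i] == 0 and s_len[i] >= 3 \
                    and gen.random() < pf[P_EL]:
                L = s_len[i]
                if i < s_hi0:
                    bucket_cnt[s_room[i] * ML1 + L] -= 1
                _canonical_into(s_seq[i], L, scratch)
                for q in range(L):
                    s_seq[i, q] = scratch[q]
                s_circ[i] = 1
                counts[6] += 1

    if phase_limit <= 4:
        return
    # ---- 5. substrate attraction ------------------------------------------
    if pf[P_AT] > 0.0:
        inv_fda = 1.0 / pf[F_DA]
        # majorant-rate opportunity counts for complexes at phase start
        kc = np.zeros(max(c_hi0, 1), dtype=np.int64)
        for cx in range(c_hi0):
            if not c_alive[cx]:
                continue
            tpl = c_tpl[cx]
            E = s_len[tpl] - c_npair[cx]
            if E <= 0:
                continue
            if s_circ[tpl]:
                pm = pf[P_AT]
            else:
                f = _eff_flt(s_seq[tpl], s_len[tpl], False, pf[F_LT],
                             rule_val, rule_topo, mot_seq, mot_len, mot_rule)
                pm = pf[P_AT] * f
            kc[cx] = _binom(gen, E, pm)
        # free strands: de-novo sites, with primer-aware continuation
        s_hi5 = ctr[0]
        for i in range(s_hi5):
            if s_state[i] != 1:
                continue
            L = s_len[i]
            if s_circ[i]:
                p_dn = pf[P_AT] * inv_fda
                pm = pf[P_AT]
            else:
                f = _eff_flt(s_seq[i], L, False, pf[F_LT], rule_val,
                             rule_topo, mot_seq, mot_len, mot_rule)
                p_dn = pf[P_AT] * f * inv_fda
                pm = pf[P_AT] * f
            kf = _binom(gen, L, p_dn)
            if kf == 0:
                continue
            newcx = -1
            for _ in range(kf):
                pos = int(gen.random() * L)
                newcx = _bind_at_pos_k(
                    gen, i, -1, pos, pf, prec, nuc,
                    s_seq, s_len, s_room, s_circ, s_state,
                    c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                    g_seq, g_len, g_start, g_owner, g_next, g_alive,
                    bucket_cnt, bucket_off, members, ctr, counts)
                if newcx >= 0:
                    break
            if newcx >= 0:
                if i < s_hi0:
                    bucket_cnt[s_room[i] * ML1 + L] -= 1
                if L > 1:
                    k2 = _binom(gen, L - 1, pm)
                    if k2 > 0:
                        _complex_attempts_k(
                            gen, newcx, k2, inv_fda, pf, prec, nuc,
                            s_seq, s_len, s_room, s_circ, s_state,
                            c_tpl, c_alive, c_first, c_nseg, c_npair,
                            c_mask, g_seq, g_len, g_start, g_owner, g_next,
                            g_alive, bucket_cnt, bucket_off, members, ctr,
                            counts)
        # complexes from the phase-start snapshot
        for cx in range(c_hi0):
            if kc[cx] > 0 and c_alive[cx]:
                _complex_attempts_k(
                    gen, cx, kc[cx], inv_fda, pf, prec, nuc,
                    s_seq, s_len, s_room, s_circ, s_state,
                    c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                    g_seq, g_len, g_start, g_owner, g_next, g_alive,
                    bucket_cnt, bucket_off, members, ctr, counts)

    if phase_limit <= 5:
        return
    # ---- 6. template-directed ligation ------------------------------------
    if pf[P_TL] > 0.0 or pf[P_TLR] > 0.0:
        c_hi6 = ctr[1]
        for cx in range(c_hi6):
            if not c_alive[cx]:
                continue
            tpl = c_tpl[cx]
            if c_nseg[cx] > 1 or (c_nseg[cx] == 1 and s_circ[tpl]
                                  and c_npair[cx] == s_len[tpl]):
                _ligate_complex_k(gen, cx, pf, rep_turn, prec, nuc,
                                  s_seq, s_len, s_room, s_circ, s_state,
                                  c_tpl, c_alive, c_first, c_nseg, c_npair,
                                  c_mask, g_seq, g_len, g_start, g_owner,
                                  g_next, g_alive, ctr, counts, scratch)

    if phase_limit <= 6:
        return
    # ---- 7. separation -----------------------------------------------------
    if pf[P_SP] > 0.0:
        g_hi7 = ctr[2]
        for j in range(g_hi7):
            if not g_alive[j]:
                continue
            if gen.random() < sep_pow[g_len[j]]:
                cx = g_owner[j]
                tpl = c_tpl[cx]
                L = s_len[tpl]
                _unlink_segment(cx, j, c_first, c_nseg, c_npair, c_mask,
                                g_next, g_len, g_start, g_alive, L,
                                s_circ[tpl] != 0)
                _release_seq(s_room[tpl], g_seq[j], g_len[j], prec, nuc,
                             s_seq, s_len, s_room, s_circ, s_state, ctr)
                _dissolve_if_empty(cx, c_alive, c_nseg, c_tpl, prec, nuc,
                                   s_seq, s_len, s_room, s_circ, s_state)
                counts[1] += 1

    if phase_limit <= 7:
        return
    # ---- 8. bond breaking ---------------------------------------------------
    if pf[P_BB] > 0.0:
        p_ds = pf[P_BB] ** 1.5
        s_hi8 = ctr[0]
        for i in range(s_hi8):
            if s_state[i] != 1 or s_len[i] < 2:
                continue
            nb = s_len[i] if s_circ[i] else s_len[i] - 1
            kb = _binom(gen, nb, pf[P_BB])
            if kb > 0:
                # at most one break per strand per step (multi-hit odds are
                # ~(L * P_BB)^2); pick the bond uniformly
                _break_free_k(gen, i, int(gen.random() * nb), prec, nuc,
                              s_seq, s_len, s_room, s_circ, s_state, ctr,
                              scratch)
                counts[4] += 1
        c_hi8 = ctr[1]
        for cx in range(c_hi8):
            if not c_alive[cx]:
                continue
            tpl = c_tpl[cx]
            L = s_len[tpl]
            nbonds = L if s_circ[tpl] else L - 1
            ds = c_npair[cx] - c_nseg[cx]
            ss = nbonds - ds
            hit_bond = -1
            hit_double = False
            if ss > 0 and _binom(gen, ss, pf[P_BB]) > 0:
                pick = int(gen.random() * ss)
                # enumerate single-stranded bonds (not inside one segment)
                idx = 0
                for b in range(nbonds):
                    inside = False
                    j = c_first[cx]
                    while j >= 0:
                        o = (b - g_start[j]) % L if s_circ[tpl] \
                            else b - g_start[j]
                        if 0 <= o < g_len[j] - 1:
                            inside = True
                            break
                        j = g_next[j]
                    if not inside:
                        if idx == pick:
                            hit_bond = b
                            break
                        idx += 1
            elif ds > 0 and _binom(gen, ds, p_ds) > 0:
                pick = int(gen.random() * ds)
                idx = 0
                for b in range(nbonds):
                    inside = False
                    j = c_first[cx]
                    while j >= 0:
                        o = (b - g_start[j]) % L if s_circ[tpl] \
                            else b - g_start[j]
                        if 0 <= o < g_len[j] - 1:
                            inside = True
                            break
                        j = g_next[j]
                    if inside:
                        if idx == pick:
                            hit_bond = b
                            hit_double = True
                            break
                        idx += 1
            if hit_bond >= 0:
                _break_complex_k(gen, cx, hit_bond, hit_double, prec, nuc,
                                 s_seq, s_len, s_room, s_circ, s_state,
                                 c_tpl, c_alive, c_first, c_nseg, c_npair,
                                 c_mask, g_seq, g_len, g_start, g_owner,
                                 g_next, g_alive, ctr, scratch)
                counts[4] += 1

    if phase_limit <= 8:
        return
    # ---- 9. terminal-residue decay -----------------------------------------
    if pf[P_NDE] > 0.0:
        p_blunt = pf[P_NDE] ** 1.5
        s_hi9 = ctr[0]
        for i in range(s_hi9):
            if s_state[i] != 1 or s_circ[i] or s_len[i] < 2:
                continue
            d5 = gen.random() < pf[P_NDE]
            d3 = gen.random() < pf[P_NDE]
            if not (d5 or d3):
                continue
            L = s_len[i]
            room = s_room[i]
            lost = (1 if d5 else 0) + (1 if d3 else 0)
            if lost >= L:
                prec[room] += L
                s_state[i] = 0
                continue
            if d5:
                for k in range(L - 1):
                    s_seq[i, k] = s_seq[i, k + 1]
            L -= lost
            s_len[i] = L
            prec[room] += lost
            if L == 1:
                nuc[room, s_seq[i, 0]] += 1
                s_state[i] = 0
            counts[5] += lost
        c_hi9 = ctr[1]
        for cx in range(c_hi9):
            if not c_alive[cx]:
                continue
            tpl = c_tpl[cx]
            if s_circ[tpl]:
                continue
            for e in range(2):
                if not c_alive[cx] or s_len[tpl] == 0:
                    break
                end3 = e == 1
                pos = s_len[tpl] - 1 if end3 else 0
                covered = (c_mask[cx] >> pos) & 1
                p = p_blunt if covered else pf[P_NDE]
                if gen.random() < p:
                    _decay_template_end_k(
                        cx, end3, prec, nuc,
                        s_seq, s_len, s_room, s_circ, s_state,
                        c_tpl, c_alive, c_first, c_nseg, c_npair, c_mask,
                        g_seq, g_len, g_start, g_owner, g_next, g_alive)
                    counts[5] += 1

    if phase_limit <= 9:
        return
    # ---- 10. movement -------------------------------------------------------
    if R > 1:
        if pf[P_MNP] > 0.0:
            for room in range(R):
                mv = _binom(gen, prec[room], pf[P_MNP])
                prec[room] -= mv
                for _ in range(mv):
                    prec[neigh[room, int(gen.random() * 4.0)]] += 1
        if pf[P_MN] > 0.0:
            for room in range(R):
                for b in range(4):
                    mv = _binom(gen, nuc[room, b], pf[P_MN])
                    nuc[room, b] -= mv
                    for _ in range(mv):
                        nuc[neigh[room, int(gen.random() * 4.0)], b] += 1
            s_hi10 = ctr[0]
            for i in range(s_hi10):
                if s_state[i] != 1:
                    continue
                if gen.random() < pf[P_MN] * inv_sqrt[s_len[i]]:
                    s_room[i] = neigh[s_room[i], int(gen.random() * 4.0)]
            c_hi10 = ctr[1]
            for cx in range(c_hi10):
                if not c_alive[cx]:
                    continue
                tpl = c_tpl[cx]
                m = s_len[tpl] + c_npair[cx]
                if gen.random() < pf[P_MN] * inv_sqrt[m]:
                    s_room[tpl] = neigh[s_room[tpl], int(gen.random() * 4.0)]


@njit(cache=True)
def _random_ligation_k(gen, room, prec, nuc, s_seq, s_len, s_room, s_circ,
                       s_state, bucket_cnt, bucket_off, members, ctr,
                       counts):
    """Join two uniformly chosen free molecules of one room 3'-to-5'."""
    ML1 = MAXLEN + 1
    base_key = room * ML1
    n_nuc = nuc[room, 0] + nuc[room, 1] + nuc[room, 2] + nuc[room, 3]
    n_str = 0
    for l in range(ML1):
        n_str += bucket_cnt[base_key + l]
    n = n_nuc + n_str
    if n < 2:
        return
    i = int(gen.random() * n)
    j = int(gen.random() * (n - 1))
    if j >= i:
        j += 1

    b1 = -1
    s1 = -1
    b2 = -1
    s2 = -1
    for which in range(2):
        idx = i if which == 0 else j
        if idx < n_nuc:
            c = 0
            for b in range(4):
                c += nuc[room, b]
                if idx < c:
                    if which == 0:
                        b1 = b
                    else:
                        b2 = b
                    break
        else:
            x = idx - n_nuc
            blk_lo = bucket_off[base_key]
            blk_hi = bucket_off[base_key + ML1]
            cnt = 0
            found = -1
            for bidx in range(blk_lo, blk_hi):
                sidx = members[bidx]
                if s_state[sidx] == 1 and s_circ[sidx] == 0:
                    if cnt == x:
                        found = sidx
                        break
                    cnt += 1
            if found < 0:
                return  # counts drifted within the phase; skip the event
            if which == 0:
                s1 = found
            else:
                s2 = found
    l1 = 1 if s1 < 0 else s_len[s1]
    l2 = 1 if s2 < 0 else s_len[s2]
    if l1 + l2 > MAXLEN:
        return
    new = ctr[0]
    ctr[0] = new + 1
    if s1 < 0:
        s_seq[new, 0] = b1
        nuc[room, b1] -= 1
    else:
        for k in range(l1):
            s_seq[new, k] = s_seq[s1, k]
        s_state[s1] = 0
        bucket_cnt[base_key + l1] -= 1
    if s2 < 0:
        s_seq[new, l1] = b2
        nuc[room, b2] -= 1
    else:
        for k in range(l2):
            s_seq[new, l1 + k] = s_seq[s2, k]
        s_state[s2] = 0
        bucket_cnt[base_key + l2] -= 1
    s_len[new] = l1 + l2
    s_room[new] = room
    s_circ[new] = 0
    s_state[new] = 1
    counts[7] += 1


# ---------------------------------------------------------------------------
# Python driver
# ---------------------------------------------------------------------------

_INV_SQRT_TAB = 1.0 / np.sqrt(np.maximum(np.arange(4096), 1))
_SEP_POW_CACHE: dict = {}
_STAT_KEYS = ("attract", "separate", "tl", "closure", "break", "end_decay",
              "circularize", "random_ligation")


def _sep_pow(p_sp: float) -> np.ndarray:
    tab = _SEP_POW_CACHE.get(p_sp)
    if tab is None:
        n = np.arange(MAXLEN + 1, dtype=np.float64)
        tab = p_sp ** np.sqrt(np.maximum(n, 1.0))
        _SEP_POW_CACHE[p_sp] = tab
    return tab


def fast_step(fs: FastState, params: Parameters,
              stats: dict | None = None) -> FastState:
    """Advance a FastState by one Monte Carlo step."""
    fs.ensure_headroom()
    pf, pi = params_vectors(params)
    ctr = np.array([fs.s_hi, fs.c_hi, fs.g_hi], dtype=np.int64)
    counts = np.zeros(10, dtype=np.int64)
    _step_kernel(fs.rng, pf, pi, fs.prec, fs.nuc, fs.neigh,
                 fs.s_seq, fs.s_len, fs.s_room, fs.s_circ, fs.s_state,
                 fs.c_tpl, fs.c_alive, fs.c_first, fs.c_nseg, fs.c_npair,
                 fs.c_mask,
                 fs.g_seq, fs.g_len, fs.g_start, fs.g_owner, fs.g_next,
                 fs.g_alive,
                 fs.bucket_cnt, fs.bucket_off, fs.rep_turn, fs.nr_turn,
                 fs.cs_rep, fs.cs_nr, fs.rule_val, fs.rule_topo,
                 fs.mot_seq, fs.mot_len, fs.mot_rule,
                 _sep_pow(params.P_SP), _INV_SQRT_TAB, ctr, counts, 99)
    fs.s_hi, fs.c_hi, fs.g_hi = int(ctr[0]), int(ctr[1]), int(ctr[2])
    fs.step_count += 1
    if stats is not None:
        for k, v in zip(_STAT_KEYS, counts.tolist()):
            if v:
                stats[k] = stats.get(k, 0) + v
    return fs


def warmup() -> None:
    """Trigger kernel compilation on a trivial system."""
    p = Parameters(N=2, T_NPB=16)
    fs = FastState(p, np.random.default_rng(0), 64, 64, 64)
    fs.add_strand("GAGUCUCU", False, 0)
    fs.add_strand("AGAGACUC", False, 0)
    fs.add_strand("GAGUCUCU", True, 1)
    fast_step(fs, p)
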