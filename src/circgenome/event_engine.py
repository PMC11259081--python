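"""One Monte Carlo step: every event, applied room by room.

Events within a step run in a fixed, documented phase order:

 1. nucleotide formation from precursors (NR-catalysed attempts first,
    consuming NR turnovers, then non-enzymatic attempts on the rest)
 2. decay of free nucleotides back to precursors
 3. random intermolecular ligation of free nucleotides / linear strands
 4. intramolecular end-to-end circularization of free linear strands
 5. substrate attraction onto templates (one opportunity per empty
    template site, with false pairing)
 6. template-directed ligation of adjacently bound segments, including
    ring closure of a complement that fully covers a circular template
 7. separation of bound segments from their template
 8. phosphodiester-bond breaking (double-stranded breaks sever both chains)
 9. terminal-residue decay at linear chain ends
10. movement of precursors, nucleotides, strands and complexes to a
    uniformly chosen toroidal neighbour room

All randomness flows through the state's single PRNG, so a run is exactly
reproducible from its seed.  Total material is conserved by every phase.
Rare events (ligation, circularization, breaking, decay, movement) are
drawn as aggregated binomials over the eligible population with uniform
assignment of the hits, which is equivalent to the per-molecule Bernoulli
description but costs one draw per phase.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np

from .model_core import (BASES, BASE_INDEX, COMPLEMENT, MIN_CIRCLE_LEN,
                         Parameters, Strand, BoundSegment, TemplateComplex,
                         SystemState, canonical_rotation)

logger = logging.getLogger("circgenome.events")

_QUARTERS = np.full(4, 0.25)
_OPPOSITE = (1, 0, 3, 2)  # up<->down, left<->right


# ---------------------------------------------------------------------------
# Probability formulas
# ---------------------------------------------------------------------------

def separation_probability(P_SP: float, n: int) -> float:
    """Probability that a duplex of ``n`` base pairs separates: P_SP**sqrt(n).

    A single pair separates with P_SP; larger duplexes are exponentially
    stickier, softened to the square root because self-folding of the
    single chains aids dissociation.
    """
    if n < 1:
        raise ValueError(f"pair count n = {n} must be >= 1")
    return P_SP ** math.sqrt(n)


def break_probability(P_BB: float, double_stranded: bool) -> float:
    """Bond-breaking probability: P_BB single-stranded, P_BB**1.5 in a duplex.

    In a double-stranded region the two parallel bonds must break together;
    the exponent 3/2 (rather than 2) reflects the synergy of the two events.
    """
    return P_BB ** 1.5 if double_stranded else P_BB


def end_decay_probability(P_NDE: float, paired_end: bool) -> float:
    """Terminal-residue decay: P_NDE for a free end, P_NDE**1.5 if paired.

    At a paired (blunt) end the two paired residues decay simultaneously,
    again with the synergistic exponent 3/2.
    """
    return P_NDE ** 1.5 if paired_end else P_NDE


def movement_probability(P_MN: float, m: int) -> float:
    """Movement probability of an RNA of mass ``m`` nucleotides: P_MN/sqrt(m).

    The square-root mass scaling follows the Zimm picture of polymer
    diffusion.  A complex moves as one unit with the mass of the template
    plus all bound substrates.
    """
    if m < 1:
        raise ValueError(f"mass m = {m} must be >= 1")
    return P_MN / math.sqrt(m)


def attraction_probability(P_AT: float, F_DA: float, F_LT: float,
                           template_is_linear: bool, de_novo: bool) -> float:
    """Per-site substrate-attraction probability.

    Circular template, primer-adjacent: P_AT; de novo divides by F_DA;
    a linear template multiplies by its efficiency factor F_LT.
    """
    p = P_AT
    if template_is_linear:
        p *= F_LT
    if de_novo:
        p /= F_DA
    return p


@lru_cache(maxsize=4096)
def _sep_prob(psp: float, n: int) -> float:
    return psp ** math.sqrt(n)


_INV_SQRT = 1.0 / np.sqrt(np.maximum(np.arange(4096), 1))


def _inv_sqrt(m: int) -> float:
    return float(_INV_SQRT[m]) if m < 4096 else 1.0 / math.sqrt(m)


# plain-dict ribozyme classification cache (bit 0 = REP, bit 1 = NR)
_RIBO_CACHES: dict = {}


def _ribo_cache(cs_rep: str, cs_nr: str) -> dict:
    key = (cs_rep, cs_nr)
    cache = _RIBO_CACHES.get(key)
    if cache is None:
        cache = _RIBO_CACHES.setdefault(key, {})
    return cache


def _ribozyme_kind(seq: str, cs_rep: str, cs_nr: str, cache: dict) -> int:
    kind = cache.get(seq)
    if kind is None:
        kind = 0
        if cs_rep in seq and len(seq) < 1.5 * len(cs_rep):
            kind |= 1
        if cs_nr in seq and len(seq) < 1.5 * len(cs_nr):
            kind |= 2
        cache[seq] = kind
    return kind


# ---------------------------------------------------------------------------
# Species-scoped effective parameters (interventions)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesScope:
    """Predicate selecting strands by topology and motif content."""

    topology: Optional[str] = None          # "linear" / "circular" / None
    contains_any: tuple = ()                # at least one motif must occur
    not_contains: tuple = ()                # none of these may occur

    def matches(self, strand: Strand) -> bool:
        from .species_classifier import contains
        topo = strand.topology
        if self.topology is not None and topo != self.topology:
            return False
        if self.contains_any and not any(
                contains(strand.seq, topo, m) for m in self.contains_any):
            return False
        if any(contains(strand.seq, topo, m) for m in self.not_contains):
            return False
        return True


class FltResolver:
    """Resolves the effective linear-template factor F_LT per strand.

    Interventions may rescale the templating efficiency of specific species
    only (e.g. linear strands carrying the REP sequence); the latest
    matching rule wins.  Results are memoized per sequence and cleared when
    the rule set changes.
    """

    def __init__(self):
        self.rules: list[tuple[SpeciesScope, float]] = []
        self._cache: dict = {}

    def add_rule(self, scope: SpeciesScope, value: float) -> None:
        self.rules.append((scope, value))
        self._cache.clear()

    def resolve(self, strand: Strand, default: float) -> float:
        if not self.rules:
            return default
        key = (strand.seq, strand.circular, default)
        hit = self._cache.get(key)
        if hit is None:
            hit = default
            for scope, value in reversed(self.rules):
                if scope.matches(strand):
                    hit = value
                    break
            self._cache[key] = hit
        return hit


@dataclass
class EventContext:
    """Room-local context handed to the event operations."""

    room: int
    params: Parameters
    rng: np.random.Generator
    rep_turnovers_left: int = 0
    nr_turnovers_left: int = 0
    flt: Optional[FltResolver] = None
    state: Optional[SystemState] = None


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _release_substrate(state: SystemState, room: int, seq: str) -> None:
    """Return a freed substrate to the system (1-mers rejoin the pool)."""
    if len(seq) == 1:
        state.nucleotides[room, BASE_INDEX[seq]] += 1
    else:
        s = state.make_strand(seq, False, room)
        state.free_strands.append(s)


def _dissolve_if_empty(state: SystemState, cx: TemplateComplex) -> bool:
    if cx.segments:
        return False
    cx.alive = False
    t = cx.template
    if len(t.seq) == 1:
        state.nucleotides[t.room, BASE_INDEX[t.seq]] += 1
    else:
        t.alive = True
        state.free_strands.append(t)
    return True


# ---------------------------------------------------------------------------
# Substrate attraction
# ---------------------------------------------------------------------------

def _empty_run_around(mask: int, pos: int, L: int, circular: bool):
    """Extent of the empty run containing ``pos``: (run_start, run_len, off).

    ``run_start`` is unwrapped (may be negative on a circular template);
    absolute positions are taken modulo L.  ``mask`` is the occupancy
    bitmask; position ``pos`` must be empty.
    """
    if mask == 0:
        return 0, L, pos
    lcount = 0
    q = pos
    while lcount < L:
        qq = (q - 1) % L if circular else q - 1
        if qq < 0 or (mask >> qq) & 1:
            break
        q = qq
        lcount += 1
    rcount = 0
    q = pos
    while rcount < L:
        qq = (q + 1) % L if circular else q + 1
        if qq >= L and not circular:
            break
        if (mask >> (qq % L)) & 1:
            break
        q = qq % L
        rcount += 1
    return pos - lcount, lcount + 1 + rcount, lcount


def _bind_at_pos(state: SystemState, target, pos: int,
                 params: Parameters, buckets: dict,
                 stats: Optional[dict], ud: Optional["_Udraw"] = None) -> bool:
    """Resolve one successful attraction at empty template position ``pos``;
    returns True if a substrate actually bound.

    The substrate is chosen uniformly among the room's eligible free
    molecules: every free nucleotide, plus every free linear strand short
    enough to fit into the empty run around ``pos``.  An oligomer's
    placement start is uniform among the starts that cover ``pos`` inside
    the run.  A nucleotide substrate pairs as the Watson-Crick complement
    of the template residue, or, with probability P_FP, binds as a
    uniformly chosen non-complementary residue (false pairing -- the
    model's mutation mechanism).  An oligomer substrate has fixed
    residues, so false pairing acts as a per-residue tolerance: every
    non-complementary position must pass an independent P_FP draw or the
    binding fails.
    """
    rng = state.rng
    if ud is None:
        ud = _Udraw(rng, 16)
    if isinstance(target, TemplateComplex):
        template = target.template
        mask = target.occupied_mask()
    else:
        template = target
        mask = 0
    L = len(template.seq)
    circular = template.circular
    room = template.room
    rs, rg, off = _empty_run_around(mask, pos, L, circular)

    nuc_counts = state.nucleotides[room]
    c0, c1, c2, c3 = nuc_counts.tolist()
    nuc_total = c0 + c1 + c2 + c3
    bucket = buckets.get(room)
    oligo_total = 0
    if bucket:
        for l, ent in bucket.items():
            if 2 <= l <= rg:
                oligo_total += ent[0]
    total = nuc_total + oligo_total
    if total == 0:
        return False
    pick = ud.below(total)
    tseq = template.seq

    if pick < nuc_total:
        ideal = COMPLEMENT[tseq[pos]]
        mism: tuple = ()
        base = ideal
        if params.P_FP > 0 and ud.u() < params.P_FP:
            others = [b for b in BASES if b != ideal]
            base = others[ud.below(3)]
            mism = (0,)
        bi = BASE_INDEX[base]
        if nuc_counts[bi] == 0:
            return False
        nuc_counts[bi] -= 1
        seg = BoundSegment(pos, base, mism)
    else:
        x = pick - nuc_total
        ent = None
        for l, e in bucket.items():
            if 2 <= l <= rg:
                if x < e[0]:
                    ent = e
                    break
                x -= e[0]
        if ent is None:
            return False
        substrate = None
        cnt = 0
        for s2 in ent[1]:
            if s2.alive and not s2.circular and s2 is not template:
                if cnt == x:
                    substrate = s2
                    break
                cnt += 1
        if substrate is None:
            return False  # count included the template itself
        l = len(substrate.seq)
        # placement start covering the chosen position, within the run
        # (on a fully empty circular template any of the l wrap placements
        # covering the position is allowed)
        if circular and rg == L and mask == 0:
            lo, hi = off - l + 1, off
        else:
            lo = max(0, off - l + 1)
            hi = min(rg - l, off)
            if hi < lo:
                return False
        start_off = lo if hi == lo else lo + ud.below(hi - lo + 1)
        start = (rs + start_off) % L if circular else rs + start_off
        sseq = substrate.seq
        P_FP = params.P_FP
        mism_list = []
        for k in range(l):
            tp = (start + l - 1 - k) % L if circular else start + l - 1 - k
            if sseq[k] != COMPLEMENT[tseq[tp]]:
                # every non-complementary residue must pass its own
                # false-pairing draw; reject as soon as one fails
                if P_FP <= 0.0 or ud.u() >= P_FP:
                    return False
                mism_list.append(k)
        substrate.alive = False
        ent[0] -= 1
        seg = BoundSegment(start, sseq, tuple(mism_list))

    if isinstance(target, TemplateComplex):
        target.append_segment(seg)
    else:
        template.alive = False
        cx = TemplateComplex(template, [seg])
        state.complexes.append(cx)
    if stats is not None:
        stats["attract"] = stats.get("attract", 0) + 1
    return True


def _is_flank(mask: int, pos: int, L: int, circular: bool) -> bool:
    """True if empty position ``pos`` abuts a bound segment."""
    if mask == 0:
        return False
    if circular:
        return bool((mask >> ((pos - 1) % L)) & 1
                    or (mask >> ((pos + 1) % L)) & 1)
    left = pos > 0 and (mask >> (pos - 1)) & 1
    right = pos + 1 < L and (mask >> (pos + 1)) & 1
    return bool(left or right)


def attract_substrate(complex_or_strand, ctx: EventContext):
    """One substrate-attraction attempt (public operation).

    Picks one empty template position uniformly, classifies it as
    primer-adjacent or de novo, draws success at the corresponding
    attraction probability, and on success binds a substrate as described
    in the step dynamics.  Requires ``ctx.state``.
    """
    state: SystemState = ctx.state
    params = ctx.params
    target = complex_or_strand
    if isinstance(target, TemplateComplex):
        template = target.template
        mask = target.occupied_mask()
    else:
        template = target
        mask = 0
    L = len(template.seq)
    empties = [p for p in range(L) if not (mask >> p) & 1]
    if not empties:
        return target
    pos = empties[int(ctx.rng.integers(len(empties)))]
    linear = not template.circular
    f_lt = 1.0
    if linear:
        f_lt = (params.F_LT if ctx.flt is None
                else ctx.flt.resolve(template, params.F_LT))
    de_novo = not _is_flank(mask, pos, L, template.circular)
    p = attraction_probability(params.P_AT, params.F_DA, f_lt, linear,
                               de_novo)
    if ctx.rng.random() < p:
        buckets: dict = {template.room: {}}
        for s in state.free_strands:
            if s.alive and not s.circular and s.room == template.room:
                ent = buckets[template.room].setdefault(len(s.seq), [0, []])
                ent[0] += 1
                ent[1].append(s)
        _bind_at_pos(state, target, pos, params, buckets, None)
    return target


# ---------------------------------------------------------------------------
# Template-directed ligation
# ---------------------------------------------------------------------------

def _merge_segments(low: BoundSegment, high: BoundSegment) -> BoundSegment:
    """Join two template-adjacent segments into one substrate.

    ``high`` covers the higher template positions; antiparallel pairing
    makes the joined substrate ``high.seq + low.seq`` (5'->3')."""
    mism = tuple(high.mismatches) + \
        tuple(m + high.n_pairs for m in low.mismatches)
    return BoundSegment(low.start, high.seq + low.seq, mism)


def _ligate_once(rng, params: Parameters, rep_turn: dict, room: int) -> bool:
    """One ligation attempt at a junction; enzymatic while turnovers last."""
    if rep_turn.get(room, 0) > 0:
        rep_turn[room] -= 1
        p = params.P_TLR
    else:
        p = params.P_TL
    return p > 0 and rng.random() < p


def template_ligate(cx: TemplateComplex, ctx: EventContext,
                    state: Optional[SystemState] = None,
                    rep_turn: Optional[dict] = None,
                    stats: Optional[dict] = None) -> TemplateComplex:
    """Attempt ligation at every junction of adjacent bound segments.

    On a circular template, a single segment covering every position gets a
    closure attempt joining its own two ends; success releases the product
    as a free circular strand and dissolves the complex.
    """
    if state is None:
        state = ctx.state
    if rep_turn is None:
        rep_turn = {ctx.room: ctx.rep_turnovers_left}
        own_turn = True
    else:
        own_turn = False
    rng = ctx.rng
    params = ctx.params
    room = cx.room
    L = len(cx.template.seq)
    circular = cx.template.circular

    if len(cx.segments) > 1:
        segs = sorted(cx.segments, key=lambda s: s.start)
        merged: list[BoundSegment] = []
        current = segs[0]
        for nxt in segs[1:]:
            cur_end = current.start + current.n_pairs
            if circular:
                cur_end %= L
            if cur_end == nxt.start and _ligate_once(rng, params, rep_turn,
                                                     room):
                current = _merge_segments(current, nxt)
                if stats is not None:
                    stats["tl"] = stats.get("tl", 0) + 1
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
        if circular and len(merged) > 1:
            last, first = merged[-1], merged[0]
            if (last.start + last.n_pairs) % L == first.start \
                    and _ligate_once(rng, params, rep_turn, room):
                merged = merged[1:-1] + [_merge_segments(last, first)]
                if stats is not None:
                    stats["tl"] = stats.get("tl", 0) + 1
        cx.segments = merged
        cx.invalidate()

    if circular and len(cx.segments) == 1 \
            and cx.segments[0].n_pairs == L and L >= MIN_CIRCLE_LEN:
        if _ligate_once(rng, params, rep_turn, room):
            seg = cx.segments[0]
            product = state.make_strand(seg.seq, True, room)
            state.free_strands.append(product)
            cx.segments = []
            cx.invalidate()
            _dissolve_if_empty(state, cx)
            if stats is not None:
                stats["closure"] = stats.get("closure", 0) + 1
    if own_turn:
        ctx.rep_turnovers_left = rep_turn[room]
    return cx


# ---------------------------------------------------------------------------
# Chain breaking / end decay (rare paths)
# ---------------------------------------------------------------------------

def _break_free_strand(state: SystemState, s: Strand, bond: int) -> None:
    """Break a free strand at ``bond`` (between positions bond and bond+1)."""
    seq = s.seq
    if s.circular:
        L = len(seq)
        cut = (bond + 1) % L
        s.seq = seq[cut:] + seq[:cut]
        s.circular = False
        return
    left, right = seq[:bond + 1], seq[bond + 1:]
    s.alive = False
    for part in (left, right):
        if part:
            _release_substrate(state, s.room, part)


def _complex_bond_classes(cx: TemplateComplex) -> tuple[list[int], list[int]]:
    """Template bond indices split into single- and double-stranded.

    Bond ``i`` joins template positions ``i`` and ``i+1`` (bond L-1 closes
    a circular template).  A bond is double-stranded when one segment
    covers both flanking positions; its parallel substrate bond breaks
    with it.
    """
    L = len(cx.template.seq)
    circular = cx.template.circular
    nbonds = L if circular else L - 1
    ds = set()
    for seg in cx.segments:
        for j in range(seg.n_pairs - 1):
            ds.add((seg.start + j) % L if circular else seg.start + j)
    ss = [b for b in range(nbonds) if b not in ds]
    return ss, sorted(ds)


def _split_segment_at(seg: BoundSegment, bond: int, L: int,
                      circular: bool) -> tuple[BoundSegment, BoundSegment]:
    """Split a segment spanning template bond ``bond`` into two.

    Returns (low, high); the substrate chain is cut at the parallel bond,
    the antiparallel orientation putting the substrate's 5' part on the
    high side.
    """
    o = (bond - seg.start) % L if circular else bond - seg.start
    n = seg.n_pairs
    cut = n - 1 - o  # substrate index boundary: seq[:cut] high, seq[cut:] low
    high_seq, low_seq = seg.seq[:cut], seg.seq[cut:]
    high_m = tuple(m for m in seg.mismatches if m < cut)
    low_m = tuple(m - cut for m in seg.mismatches if m >= cut)
    low = BoundSegment(seg.start, low_seq, low_m)
    high = BoundSegment((bond + 1) % L if circular else bond + 1,
                        high_seq, high_m)
    return low, high


def _open_circular_template(cx: TemplateComplex, bond: int) -> None:
    """Open a circular template at ``bond``; remap segment positions."""
    t = cx.template
    L = len(t.seq)
    cut = (bond + 1) % L
    t.seq = t.seq[cut:] + t.seq[:cut]
    t.circular = False
    for seg in cx.segments:
        seg.start = (seg.start - cut) % L
    cx.invalidate()


def _break_complex(state: SystemState, cx: TemplateComplex, bond: int,
                   double: bool) -> None:
    """Break the template of a complex at ``bond``.

    A double-stranded break severs the spanning segment too; a
    single-stranded template bond never has a spanning segment (it would
    be double-stranded otherwise).
    """
    L = len(cx.template.seq)
    circular = cx.template.circular
    if double:
        for seg in cx.segments:
            o = (bond - seg.start) % L if circular else bond - seg.start
            if 0 <= o < seg.n_pairs - 1:
                low, high = _split_segment_at(seg, bond, L, circular)
                cx.segments.remove(seg)
                cx.segments.extend([low, high])
                cx.invalidate()
                break
    if circular:
        _open_circular_template(cx, bond)
        _dissolve_if_empty(state, cx)
        return
    t = cx.template
    left_seq, right_seq = t.seq[:bond + 1], t.seq[bond + 1:]
    left_segs = [s for s in cx.segments if s.start + s.n_pairs - 1 <= bond]
    right_segs = [s for s in cx.segments if s.start > bond]
    cx.alive = False
    room = t.room
    for seq, segs, shift in ((left_seq, left_segs, 0),
                             (right_seq, right_segs, bond + 1)):
        if not seq:
            continue
        if segs:
            nt = state.make_strand(seq, False, room)
            nt.alive = False
            for s in segs:
                s.start -= shift
            state.complexes.append(TemplateComplex(nt, segs))
        else:
            _release_substrate(state, room, seq)


def _decay_template_end(state: SystemState, cx: TemplateComplex,
                        end3: bool) -> None:
    """Remove a terminal template residue (and its blunt-paired partner)."""
    t = cx.template
    L = len(t.seq)
    pos = L - 1 if end3 else 0
    covering = None
    for seg in cx.segments:
        if seg.start <= pos < seg.start + seg.n_pairs:
            covering = seg
            break
    released = 1
    if covering is not None:
        # blunt pairing: the partner residue is terminal in the substrate
        if pos == covering.start + covering.n_pairs - 1:
            new_seq = covering.seq[1:]       # drop substrate 5' residue
            new_m = tuple(m - 1 for m in covering.mismatches if m >= 1)
            new_start = covering.start
        else:
            new_seq = covering.seq[:-1]      # drop substrate 3' residue
            new_m = tuple(m for m in covering.mismatches if m < len(new_seq))
            new_start = covering.start + 1
        cx.segments.remove(covering)
        if new_seq:
            cx.segments.append(BoundSegment(new_start, new_seq, new_m))
        released = 2
    t.seq = t.seq[:-1] if end3 else t.seq[1:]
    if not end3:
        for seg in cx.segments:
            seg.start -= 1
    cx.invalidate()
    state.precursors[t.room] += released
    if not t.seq:
        cx.alive = False
    else:
        _dissolve_if_empty(state, cx)


def _random_ligation(state: SystemState, room: int, buckets: dict,
                     rng, stats) -> None:
    """Join two uniformly chosen free molecules of one room 3'-to-5'."""
    nuc_counts = state.nucleotides[room]
    strands = [s for ent in buckets.get(room, {}).values() for s in ent[1]
               if s.alive and not s.circular]
    n_nuc = int(nuc_counts.sum())
    n = n_nuc + len(strands)
    if n < 2:
        return
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1

    def take(idx):
        if idx < n_nuc:
            c = 0
            for bi in range(4):
                c += int(nuc_counts[bi])
                if idx < c:
                    return BASES[bi], None
            raise AssertionError("unreachable")
        return None, strands[idx - n_nuc]

    b1, s1 = take(i)
    b2, s2 = take(j)
    seq1 = b1 if s1 is None else s1.seq
    seq2 = b2 if s2 is None else s2.seq
    bucket = buckets.get(room, {})
    for b, s in ((b1, s1), (b2, s2)):
        if s is None:
            nuc_counts[BASE_INDEX[b]] -= 1
        else:
            s.alive = False
            ent = bucket.get(len(s.seq))
            if ent is not None and ent[0] > 0:
                ent[0] -= 1
    state.free_strands.append(state.make_strand(seq1 + seq2, False, room))
    if stats is not None:
        stats["random_ligation"] = stats.get("random_ligation", 0) + 1


# ---------------------------------------------------------------------------
# Aggregated-draw helpers
# ---------------------------------------------------------------------------

class _Udraw:
    """Buffered uniform variates from the run's single PRNG stream.

    Scalar draws from a numpy Generator cost ~1 microsecond each; the hot
    event loops instead consume a pre-drawn block, refilled on demand, so
    the per-draw cost is a list index.  Determinism is unaffected: the
    stream and consumption order are fixed by the state.
    """

    __slots__ = ("rng", "buf", "i", "n")

    def __init__(self, rng, n: int = 4096):
        self.rng = rng
        self.n = n
        self.buf = rng.random(n).tolist()
        self.i = 0

    def u(self) -> float:
        i = self.i
        if i >= self.n:
            self.buf = self.rng.random(self.n).tolist()
            i = 0
        self.i = i + 1
        return self.buf[i]

    def below(self, k: int) -> int:
        """Uniform integer in [0, k)."""
        return int(self.u() * k)


def _binomial_hits(rng, total: int, p: float) -> np.ndarray:
    """Locations of Binomial(total, p) successes, uniform over [0, total)."""
    if total <= 0 or p <= 0.0:
        return np.empty(0, dtype=np.int64)
    k = int(rng.binomial(total, p))
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(total, size=min(k, total), replace=False)


# ---------------------------------------------------------------------------
# The step
# ---------------------------------------------------------------------------

def step(state: SystemState, params: Parameters,
         flt: Optional[FltResolver] = None,
         stats: Optional[dict] = None) -> SystemState:
    """Advance the system by one Monte Carlo step (in place)."""
    rng = state.rng
    prec = state.precursors
    nucs = state.nucleotides
    n_rooms = state.N * state.N
    free = state.free_strands
    cxs = state.complexes
    cs_rep, cs_nr = params.CS_REP, params.CS_NR
    ribo = _ribo_cache(cs_rep, cs_nr)
    min_cs = min(len(cs_rep), len(cs_nr))

    # --- gather pass: per-room bookkeeping at step start ------------------
    rep_turn: dict[int, int] = {}
    nr_turn: dict[int, int] = {}
    buckets: dict[int, dict[int, list[Strand]]] = {}
    n_strand_room = np.zeros(n_rooms, dtype=np.int64)
    T_REP, T_NR = params.T_REP, params.T_NR

    def count_ribozyme(seq: str, room: int) -> None:
        kind = _ribozyme_kind(seq, cs_rep, cs_nr, ribo)
        if kind:
            if kind & 1:
                rep_turn[room] = rep_turn.get(room, 0) + T_REP
            if kind & 2:
                nr_turn[room] = nr_turn.get(room, 0) + T_NR

    for s in free:
        r = s.room
        n_strand_room[r] += 1
        if not s.circular:
            l = len(s.seq)
            b = buckets.get(r)
            if b is None:
                b = buckets[r] = {}
            ent = b.get(l)
            if ent is None:
                b[l] = [1, [s]]
            else:
                ent[0] += 1
                ent[1].append(s)
            if l >= min_cs:
                count_ribozyme(s.seq, r)
    for cx in cxs:
        t = cx.template
        if not t.circular and len(t.seq) >= min_cs:
            count_ribozyme(t.seq, cx.room)
        for seg in cx.segments:
            if seg.n_pairs >= min_cs:
                count_ribozyme(seg.seq, cx.room)

    # --- 1. nucleotide formation ------------------------------------------
    attempted = None
    if nr_turn and params.P_NFR > 0:
        attempted = {}
        for room, t in nr_turn.items():
            avail = int(prec[room])
            attempts = min(t, avail)
            if attempts <= 0:
                continue
            succ = int(rng.binomial(attempts, params.P_NFR))
            if succ:
                prec[room] -= succ
                nucs[room] += rng.multinomial(succ, _QUARTERS)
            attempted[room] = attempts - succ  # tried, stayed precursor
    if params.P_NF > 0:
        pool = prec.copy() if attempted else prec
        if attempted:
            for room, res in attempted.items():
                pool[room] = max(0, pool[room] - res)
        formed = rng.binomial(pool, params.P_NF)
        if int(formed.sum()):
            prec -= formed
            nucs += rng.multinomial(formed, _QUARTERS)

    # --- 2. free-nucleotide decay -----------------------------------------
    if params.P_ND > 0:
        dec = rng.binomial(nucs, params.P_ND)
        nucs -= dec
        prec += dec.sum(axis=1)

    # --- 3. random intermolecular ligation --------------------------------
    if params.P_RL > 0:
        n_mol = nucs.sum(axis=1) + n_strand_room
        total = int(n_mol.sum())
        hits = _binomial_hits(rng, total, params.P_RL)
        if hits.size:
            cum = np.cumsum(n_mol)
            rooms = np.searchsorted(cum, hits, side="right")
            for room in rooms:
                _random_ligation(state, int(room), buckets, rng, stats)

    # --- 4. circularization -----------------------------------------------
    if params.P_EL > 0:
        cands = [s for s in free
                 if s.alive and not s.circular and len(s.seq) >= MIN_CIRCLE_LEN]
        for i in _binomial_hits(rng, len(cands), params.P_EL):
            s = cands[i]
            if s.alive and not s.circular:
                ent = buckets.get(s.room, {}).get(len(s.seq))
                if ent is not None and ent[0] > 0:
                    ent[0] -= 1  # no longer substrate-eligible
                s.seq = canonical_rotation(s.seq)
                s.circular = True
                if stats is not None:
                    stats["circularize"] = stats.get("circularize", 0) + 1

    # --- 5. substrate attraction ------------------------------------------
    if params.P_AT > 0:
        _phase_attraction(state, params, flt, buckets, free, cxs, rng, stats)
    # drop strands consumed as templates/substrates now, so that a complex
    # dissolving later this step re-lists its template without duplication
    state.free_strands = [s for s in state.free_strands if s.alive]

    # --- 6. template-directed ligation ------------------------------------
    if params.P_TL > 0 or params.P_TLR > 0:
        ctx = EventContext(0, params, rng)
        for cx in list(state.complexes):
            if not cx.alive:
                continue
            nseg = len(cx.segments)
            if nseg > 1 or (nseg == 1 and cx.template.circular
                            and cx.segments[0].n_pairs == len(cx.template.seq)):
                ctx.room = cx.room
                template_ligate(cx, ctx, state=state, rep_turn=rep_turn,
                                stats=stats)

    # --- 7. separation -----------------------------------------------------
    if params.P_SP > 0:
        by_n: dict[int, list] = {}
        for cx in state.complexes:
            if cx.alive:
                for seg in cx.segments:
                    by_n.setdefault(seg.n_pairs, []).append((cx, seg))
        for n, pairs in by_n.items():
            for i in _binomial_hits(rng, len(pairs), _sep_prob(params.P_SP, n)):
                cx, seg = pairs[i]
                if seg not in cx.segments:
                    continue
                cx.segments.remove(seg)
                cx.invalidate()
                _release_substrate(state, cx.room, seg.seq)
                _dissolve_if_empty(state, cx)
                if stats is not None:
                    stats["separate"] = stats.get("separate", 0) + 1

    # --- 8. bond breaking --------------------------------------------------
    if params.P_BB > 0:
        _phase_bond_breaking(state, params, rng, stats)

    # --- 9. terminal-residue decay ----------------------------------------
    if params.P_NDE > 0:
        _phase_end_decay(state, params, rng, stats)

    # --- 10. movement ------------------------------------------------------
    state.free_strands = [s for s in state.free_strands if s.alive]
    state.complexes = [cx for cx in state.complexes if cx.alive]
    _phase_movement(state, params, rng)

    state.step += 1
    if stats is not None and logger.isEnabledFor(logging.DEBUG):
        logger.debug("step %d: %s", state.step, stats)
    return state


def _phase_attraction(state, params, flt, buckets, free, cxs, rng,
                      stats) -> None:
    """One attraction opportunity per empty template site per step.

    Site opportunities are drawn as binomials per template over the site
    classes present at phase start (a fully free strand exposes only
    de-novo sites; a partially covered template exposes primer-adjacent
    flank sites and de-novo interior sites); each success binds one
    substrate at a uniformly chosen site of its class.
    """
    P_AT, F_DA = params.P_AT, params.F_DA
    base_flt = params.F_LT
    has_rules = flt is not None and flt.rules
    inv_fda = 1.0 / F_DA
    ud = _Udraw(rng)

    def complex_attempts(cx: TemplateComplex, k: int) -> None:
        """``k`` majorant-rate site attempts on a complex.

        Each attempt picks one empty position uniformly; a primer-adjacent
        (flank) position binds at the majorant rate, a de-novo position is
        thinned by the extra 1/F_DA factor.  Binding updates the occupancy
        immediately, so a substrate landing next to a fresh segment within
        the same step already enjoys the primer effect -- the within-step
        elongation cascade.
        """
        t = cx.template
        L = len(t.seq)
        circular = t.circular
        for _ in range(k):
            mask = cx.occupied_mask()
            n_empty = L - cx.n_paired()
            if n_empty <= 0:
                break
            while True:
                pos = ud.below(L)
                if not (mask >> pos) & 1:
                    break
            if not _is_flank(mask, pos, L, circular) \
                    and ud.u() >= inv_fda:
                continue
            _bind_at_pos(state, cx, pos, params, buckets, stats, ud)

    # snapshot the complexes existing at phase start (complexes created by
    # free-strand binds below get their opportunities there)
    nc = len(cxs)
    if nc:
        pmaj = np.empty(nc)
        nsites = np.empty(nc, dtype=np.int64)
        for i in range(nc):
            cx = cxs[i]
            t = cx.template
            if t.circular:
                pmaj[i] = P_AT
            else:
                f = flt.resolve(t, base_flt) if has_rules else base_flt
                pmaj[i] = P_AT * f
            nsites[i] = len(t.seq) - cx.n_paired()
        kc = rng.binomial(nsites, pmaj)

    # free strands: every position is a de-novo site; once the first
    # substrate binds, the remaining positions get their opportunity at
    # the complex (primer-aware) rates
    nf = len(free)
    if nf:
        ps = np.empty(nf)
        ns = np.empty(nf, dtype=np.int64)
        circ0 = np.empty(nf, dtype=bool)
        for i, s in enumerate(free):
            ns[i] = len(s.seq)
            circ0[i] = s.circular
            if s.circular:
                ps[i] = P_AT / F_DA
            else:
                f = flt.resolve(s, base_flt) if has_rules else base_flt
                ps[i] = P_AT * f / F_DA
        ks = rng.binomial(ns, ps)
        for i in np.nonzero(ks)[0]:
            s = free[i]
            if not s.alive or s.circular != circ0[i]:
                continue  # consumed, or circularized after the snapshot
            L = int(ns[i])
            bound = False
            for _ in range(int(ks[i])):
                pos = ud.below(L)
                if _bind_at_pos(state, s, pos, params, buckets, stats, ud):
                    bound = True
                    break
            if bound and L > 1:
                cx = state.complexes[-1]
                pm = P_AT if s.circular else ps[i] * F_DA
                k2 = int(rng.binomial(L - 1, pm))
                if k2:
                    complex_attempts(cx, k2)

    # complexes existing at phase start
    if nc:
        for i in np.nonzero(kc)[0]:
            cx = cxs[i]
            if cx.alive:
                complex_attempts(cx, int(kc[i]))


def _phase_bond_breaking(state, params, rng, stats) -> None:
    P_BB = params.P_BB
    P_BBd = P_BB ** 1.5
    # free strands: all bonds single-stranded.  Each strand exposes
    # len(seq) bond slots (a majorant: a linear strand's last slot is
    # vacuous and simply discarded), so hits can be drawn in one binomial.
    fs = state.free_strands
    if fs:
        nb = np.fromiter(map(len, (s.seq for s in fs)),
                         dtype=np.int64, count=len(fs))
        cum = np.cumsum(nb)
        hits = _binomial_hits(rng, int(cum[-1]), P_BB)
        if hits.size:
            hits = np.sort(hits)[::-1]  # process high bonds first
            owners = np.searchsorted(cum, hits, side="right")
            for loc, i in zip(hits.tolist(), owners.tolist()):
                s = fs[i]
                if not s.alive:
                    continue
                bond = int(loc - (cum[i - 1] if i else 0))
                if bond >= (len(s.seq) if s.circular else len(s.seq) - 1):
                    continue  # vacuous slot, or strand shrank this phase
                _break_free_strand(state, s, bond)
                if stats is not None:
                    stats["break"] = stats.get("break", 0) + 1
    # complexes: aggregate single- and double-stranded bond counts
    live = [cx for cx in state.complexes if cx.alive]
    if live:
        ss_n = np.empty(len(live), dtype=np.int64)
        ds_n = np.empty(len(live), dtype=np.int64)
        for i, cx in enumerate(live):
            L = len(cx.template.seq)
            nbonds = L if cx.template.circular else L - 1
            ds = cx.n_paired() - len(cx.segments)
            ds_n[i] = ds
            ss_n[i] = nbonds - ds
        for counts, p, double in ((ss_n, P_BB, False), (ds_n, P_BBd, True)):
            total = int(counts.sum())
            hits = _binomial_hits(rng, total, p)
            if not hits.size:
                continue
            cum = np.cumsum(counts)
            owners = np.searchsorted(cum, hits, side="right")
            for loc, i in zip(hits.tolist(), owners.tolist()):
                cx = live[i]
                if not cx.alive:
                    continue
                idx = int(loc - (cum[i - 1] if i else 0))
                ss, ds = _complex_bond_classes(cx)
                bonds = ds if double else ss
                if idx >= len(bonds):
                    continue  # complex changed earlier this phase
                _break_complex(state, cx, bonds[idx], double)
                if stats is not None:
                    stats["break"] = stats.get("break", 0) + 1


def _phase_end_decay(state, params, rng, stats) -> None:
    P = params.P_NDE
    Pd = P ** 1.5
    fs = state.free_strands
    if fs:
        # two end slots per strand; slots of circular strands are vacuous
        hits = _binomial_hits(rng, 2 * len(fs), P)
        if hits.size:
            per: dict[int, list[int]] = {}
            for loc in np.sort(hits).tolist():
                per.setdefault(loc // 2, []).append(loc % 2)
            for i, ends in per.items():
                s = fs[i]
                if not s.alive or s.circular:
                    continue
                seq = s.seq
                lost = len(ends)
                if lost >= len(seq):
                    s.alive = False
                    state.precursors[s.room] += len(seq)
                    continue
                if 1 in ends:
                    seq = seq[:-1]
                if 0 in ends:
                    seq = seq[1:]
                state.precursors[s.room] += lost
                if len(seq) == 1:
                    s.alive = False
                    state.nucleotides[s.room, BASE_INDEX[seq]] += 1
                else:
                    s.seq = seq
                if stats is not None:
                    stats["end_decay"] = stats.get("end_decay", 0) + lost
    # linear templates inside complexes: a covered (blunt-paired) end takes
    # its partner residue with it at P_NDE**1.5; substrate ends paired to
    # internal template residues are protected.
    plain: list = []
    paired: list = []
    for cx in state.complexes:
        if not cx.alive or cx.template.circular:
            continue
        mask = cx.occupied_mask()
        L = len(cx.template.seq)
        (paired if mask & 1 else plain).append((cx, False))
        (paired if (mask >> (L - 1)) & 1 else plain).append((cx, True))
    for ends, p in ((plain, P), (paired, Pd)):
        for i in _binomial_hits(rng, len(ends), p):
            cx, end3 = ends[i]
            if cx.alive and cx.template.seq:
                _decay_template_end(state, cx, end3)
                if stats is not None:
                    stats["end_decay"] = stats.get("end_decay", 0) + 1


def _phase_movement(state, params, rng) -> None:
    neigh = state.neighbours
    n_rooms = neigh.shape[0]
    if n_rooms > 1 and params.P_MNP > 0:
        _move_grid(state.precursors, params.P_MNP, neigh, rng)
    if n_rooms > 1 and params.P_MN > 0:
        flat = state.nucleotides.reshape(-1)
        movers = rng.binomial(flat, params.P_MN)
        if int(movers.sum()):
            dirs = rng.multinomial(movers, _QUARTERS).reshape(n_rooms, 4, 4)
            state.nucleotides -= movers.reshape(n_rooms, 4)
            for d in range(4):
                src = neigh[:, _OPPOSITE[d]]
                state.nucleotides += dirs[src, :, d]
        # strands and complexes: draw hits at the nucleotide rate P_MN and
        # thin each by 1/sqrt(mass) -- exactly Bernoulli(P_MN/sqrt(m)) per
        # molecule without touching the whole population
        P_MN = params.P_MN
        nf = len(state.free_strands)
        ntot = nf + len(state.complexes)
        for i in _binomial_hits(rng, ntot, P_MN).tolist():
            mol = state.free_strands[i] if i < nf \
                else state.complexes[i - nf]
            m = len(mol.seq) if isinstance(mol, Strand) else mol.mass()
            if m > 1 and rng.random() >= _inv_sqrt(m):
                continue
            mol.room = int(neigh[mol.room, int(rng.integers(4))])


def _move_grid(grid: np.ndarray, p: float, neigh: np.ndarray, rng) -> None:
    movers = rng.binomial(grid, p)
    if int(movers.sum()) == 0:
        return
    dirs = rng.multinomial(movers, _QUARTERS)  # (n_rooms, 4)
    grid -= movers
    for d in range(4):
        src = neigh[:, _OPPOSITE[d]]
        grid += dirs[src, d]
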