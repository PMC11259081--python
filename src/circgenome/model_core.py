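"""Domain types and parameters for the circular-genome RNA-world model.

The model lives on an ``N x N`` toroidal grid of "rooms".  Each room holds
nucleotide precursors, free (activated) nucleotides and RNA molecules; RNA
molecules are linear or circular strands, possibly engaged in a template
complex with substrate segments base-paired onto them.  The total material
of the system, counted in nucleotide equivalents, is conserved by every
event: precursors, free nucleotides and every strand residue (templates and
bound substrates alike) always sum to the initial precursor endowment plus
whatever mass was inoculated by the scenario.

This module defines the data types, the full default parameter set and the
validation / sanity rules.  Event dynamics live in
:mod:`circgenome.event_engine`.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import yaml

BASES = "AGCU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Minimum ring size.  One- or two-residue rings are chemically implausible
#: and the dynamics never need them; circularization and ring-forming
#: ligation enforce this floor.
MIN_CIRCLE_LEN = 3


def _check_rna(seq: str, what: str = "sequence") -> None:
    for ch in seq:
        if ch not in COMPLEMENT:
            raise ValueError(f"invalid residue {ch!r} in {what}: "
                             f"RNA sequences use A, G, C, U")


# ---------------------------------------------------------------------------
# Parameters (Table of model constants)
# ---------------------------------------------------------------------------

_PROB_FIELDS = ("P_AT", "P_BB", "P_EL", "P_FP", "P_MN", "P_MNP", "P_ND",
                "P_NDE", "P_NF", "P_NFR", "P_RL", "P_SP", "P_TL", "P_TLR")
_SEQ_FIELDS = ("CS_REP", "CS_NR", "CS_CT")


@dataclass
class Parameters:
    """The full parameter record of the model.

    Probabilities are per event-opportunity per Monte Carlo step.  ``N`` is
    the grid side length, ``T_NPB`` the initial precursor endowment in
    nucleotide equivalents, ``T_REP``/``T_NR`` the catalytic turnovers per
    functional ribozyme per step, ``F_DA`` the penalty factor for de-novo
    substrate attraction (>= 1), ``F_LT`` the templating-efficiency factor
    of a linear RNA relative to a circular one (in [0, 1]) and ``CS_*`` the
    characteristic sequences of the replicase (REP), the nucleotide
    synthetase (NR) and the functionless control RNA.
    """

    P_AT: float = 0.5        # template attracting a substrate
    P_BB: float = 5e-6       # phosphodiester bond breaking within a chain
    P_EL: float = 1e-7       # end-to-end ligation (circularization)
    P_FP: float = 0.001      # false base-pairing during attraction
    P_MN: float = 0.002      # movement of nucleotides (and RNA, mass-scaled)
    P_MNP: float = 0.01      # movement of nucleotide precursors
    P_ND: float = 0.05       # free nucleotide decaying into its precursor
    P_NDE: float = 0.001     # terminal residue decaying at a chain end
    P_NF: float = 0.005      # nucleotide forming from a precursor (non-enzymatic)
    P_NFR: float = 0.9       # nucleotide formation catalysed by NR
    P_RL: float = 1e-7       # random intermolecular ligation
    P_SP: float = 0.5        # separation of a single base pair
    P_TL: float = 0.01       # template-directed ligation (non-enzymatic)
    P_TLR: float = 0.9       # template-directed ligation catalysed by REP
    N: int = 30              # grid side length
    T_NPB: int = 100_000     # initial nucleotide-precursor count
    T_REP: int = 10          # catalytic turnovers per REP per step
    T_NR: int = 10           # catalytic turnovers per NR per step
    F_DA: float = 5.0        # de-novo attraction penalty factor (>= 1)
    F_LT: float = 0.5        # linear-template efficiency factor (in [0, 1])
    CS_REP: str = "GAGUCUCU"
    CS_NR: str = "UGAUGCAG"
    CS_CT: str = "ACGAACUG"

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Parameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self) -> str:
        """Flat key/value YAML, keys named exactly as the model symbols."""
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "Parameters":
        data = yaml.safe_load(io.StringIO(text))
        if not isinstance(data, dict):
            raise ValueError("parameter file must be a flat mapping")
        return cls.from_dict(data)

    def replace(self, **overrides) -> "Parameters":
        return dataclasses.replace(self, **overrides)


def make_default_parameters() -> Parameters:
    """Return the default parameter record."""
    return Parameters()


def validate_parameters(p: Parameters) -> list[str]:
    """Hard-validate ranges and return soft sanity warnings.

    Range violations (a probability outside [0, 1], ``F_DA < 1`` ...)
    raise :class:`ValueError` naming the offending field.  Violations of
    the parameter-ordering guidelines (catalysed reactions much faster
    than the non-enzymatic ones, template-directed ligation much faster
    than random ligation, end decay slower than free-nucleotide decay,
    nucleotides slower-moving than precursors) are returned as a list of
    warning strings: scenarios deliberately break them mid-run (e.g.
    switching a ribozyme off with ``P_TLR = 0``), so they must not be
    fatal.
    """
    for name in _PROB_FIELDS:
        v = getattr(p, name)
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} = {v!r} outside [0, 1]")
    if p.F_DA < 1:
        raise ValueError(f"F_DA = {p.F_DA!r} must be >= 1")
    if not (0.0 <= p.F_LT <= 1.0):
        raise ValueError(f"F_LT = {p.F_LT!r} outside [0, 1]")
    if p.N < 1:
        raise ValueError(f"N = {p.N!r} must be >= 1")
    if p.T_NPB < 0:
        raise ValueError(f"T_NPB = {p.T_NPB!r} must be >= 0")
    if p.T_REP < 0:
        raise ValueError(f"T_REP = {p.T_REP!r} must be >= 0")
    if p.T_NR < 0:
        raise ValueError(f"T_NR = {p.T_NR!r} must be >= 0")
    for name in _SEQ_FIELDS:
        _check_rna(getattr(p, name), name)

    warnings: list[str] = []
    # ">>" is read as "at least an order of magnitude larger".
    if not p.P_TLR >= 10 * p.P_TL:
        warnings.append(f"P_TLR >> P_TL violated (P_TLR={p.P_TLR}, P_TL={p.P_TL})")
    if not p.P_NFR >= 10 * p.P_NF:
        warnings.append(f"P_NFR >> P_NF violated (P_NFR={p.P_NFR}, P_NF={p.P_NF})")
    if not p.P_TL >= 10 * p.P_RL:
        warnings.append(f"P_TL >> P_RL violated (P_TL={p.P_TL}, P_RL={p.P_RL})")
    if not p.P_NDE < p.P_ND:
        warnings.append(f"P_NDE < P_ND violated (P_NDE={p.P_NDE}, P_ND={p.P_ND})")
    if not p.P_MN < p.P_MNP:
        warnings.append(f"P_MN < P_MNP violated (P_MN={p.P_MN}, P_MNP={p.P_MNP})")
    return warnings


# ---------------------------------------------------------------------------
# Molecules
# ---------------------------------------------------------------------------

def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation of ``seq``.

    Circular sequences are stored in this canonical rotation so that equal
    rings compare equal regardless of where ligation closed them.
    """
    if len(seq) <= 1:
        return seq
    doubled = seq + seq
    n = len(seq)
    return min(doubled[i:i + n] for i in range(n))


class Strand:
    """A linear or circular RNA molecule.

    Sequences are stored 5'->3'; positions are 0-based; circular positions
    are taken modulo the length.  Circular sequences are canonicalized to
    their lexicographically smallest rotation.
    """

    __slots__ = ("seq", "circular", "id", "room", "alive")

    def __init__(self, seq: str, circular: bool = False, id: int = -1,
                 room: int = 0):
        _check_rna(seq)
        if circular:
            if len(seq) < MIN_CIRCLE_LEN:
                raise ValueError(
                    f"circular strand of length {len(seq)} < {MIN_CIRCLE_LEN}")
            seq = canonical_rotation(seq)
        elif len(seq) < 1:
            raise ValueError("empty linear strand")
        self.seq = seq
        self.circular = circular
        self.id = id
        self.room = room
        # True while the strand is free in a room; cleared when it is
        # consumed (bound into a complex, ligated away, degraded).
        self.alive = True

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def topology(self) -> str:
        return "circular" if self.circular else "linear"

    def same_species(self, other: "Strand") -> bool:
        return self.circular == other.circular and self.seq == other.seq

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Strand({self.seq!r}, {self.topology}, room={self.room})"


class BoundSegment:
    """A linear substrate base-paired onto a stretch of a template.

    The segment occupies template positions ``start .. start+n-1`` (modulo
    the template length for circular templates).  The substrate sequence is
    stored 5'->3'; being antiparallel, substrate residue ``k`` pairs with
    template position ``start + n - 1 - k``.  ``mismatches`` holds the
    substrate indices whose residue does not Watson-Crick-complement the
    template residue it sits on; mismatched residues still count as paired
    for duplex-size purposes.
    """

    __slots__ = ("start", "seq", "mismatches", "n_pairs")

    def __init__(self, start: int, seq: str, mismatches: Iterable[int] = ()):
        if len(seq) < 1:
            raise ValueError("empty bound segment")
        self.start = start
        self.seq = seq
        self.n_pairs = len(seq)
        self.mismatches = frozenset(mismatches)
        if self.mismatches and max(self.mismatches) >= len(seq):
            raise ValueError("mismatch index outside segment")

    def positions(self, template_len: int, circular: bool) -> list[int]:
        """Template positions covered by this segment, in ascending offset."""
        if circular:
            return [(self.start + k) % template_len for k in range(len(self.seq))]
        return list(range(self.start, self.start + len(self.seq)))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BoundSegment(start={self.start}, seq={self.seq!r})"


class TemplateComplex:
    """A template strand plus the substrate segments bound to it."""

    __slots__ = ("template", "segments", "alive", "_occ_mask", "_runs",
                 "_npaired")

    def __init__(self, template: Strand, segments: Optional[list] = None):
        self.template = template
        self.segments = segments if segments is not None else []
        self.alive = True
        self._occ_mask = None   # lazily computed occupancy bitmask
        self._runs = None       # lazily computed empty runs
        self._npaired = sum(s.n_pairs for s in self.segments)
        self._check()

    def _check(self) -> None:
        L = len(self.template)
        if len(self.segments) == 1:
            seg = self.segments[0]
            if seg.n_pairs > L or (not self.template.circular and
                                   (seg.start < 0 or
                                    seg.start + seg.n_pairs > L)):
                raise ValueError("segment outside template")
            return
        seen = set()
        for seg in self.segments:
            pos = seg.positions(L, self.template.circular)
            if not self.template.circular:
                if seg.start < 0 or seg.start + seg.n_pairs > L:
                    raise ValueError("segment outside linear template")
            if seen & set(pos):
                raise ValueError("overlapping bound segments")
            seen.update(pos)
        if len(seen) > L:
            raise ValueError("more paired positions than template length")

    @property
    def room(self) -> int:
        return self.template.room

    @room.setter
    def room(self, value: int) -> None:
        self.template.room = value

    def invalidate(self) -> None:
        self._occ_mask = None
        self._runs = None
        self._npaired = sum(s.n_pairs for s in self.segments)

    def append_segment(self, seg: BoundSegment) -> None:
        """Attach a segment, updating the cached occupancy incrementally."""
        self.segments.append(seg)
        self._npaired += seg.n_pairs
        self._runs = None
        if self._occ_mask is not None:
            L = len(self.template.seq)
            mask = self._occ_mask
            if self.template.circular:
                for k in range(seg.n_pairs):
                    mask |= 1 << ((seg.start + k) % L)
            else:
                mask |= ((1 << seg.n_pairs) - 1) << seg.start
            self._occ_mask = mask

    def occupied_mask(self) -> int:
        """Occupancy of template positions as a bitmask (bit i = position i)."""
        if self._occ_mask is None:
            L = len(self.template)
            mask = 0
            for seg in self.segments:
                for p in seg.positions(L, self.template.circular):
                    mask |= 1 << p
            self._occ_mask = mask
        return self._occ_mask

    def n_paired(self) -> int:
        return self._npaired

    def empty_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of unpaired template positions as (start, length).

        For a circular template a run may wrap around the origin (its start
        plus length may exceed the template length; positions are taken
        modulo the length).  A fully empty template yields ``[(0, L)]``.
        """
        if self._runs is not None:
            return self._runs
        L = len(self.template)
        full = (1 << L) - 1
        empty = full & ~self.occupied_mask()
        runs: list[tuple[int, int]] = []
        if empty == full:
            runs = [(0, L)]
        else:
            m = empty
            while m:
                start = (m & -m).bit_length() - 1
                t = m >> start
                length = (~t & (t + 1)).bit_length() - 1
                runs.append((start, length))
                m &= ~(((1 << length) - 1) << start)
            if self.template.circular and len(runs) >= 2:
                first, last = runs[0], runs[-1]
                if first[0] == 0 and last[0] + last[1] == L:
                    runs = runs[1:-1] + [(last[0], last[1] + first[1])]
        self._runs = runs
        return runs

    def site_classes(self) -> tuple[int, int]:
        """Counts of (primer-adjacent, de novo) attraction sites.

        An empty position immediately neighbouring a bound segment is a
        primer-adjacent site; all other empty positions are de novo sites.
        On a fully empty template every position is de novo.
        """
        runs = self.empty_runs()
        L = len(self.template)
        circular = self.template.circular
        n_empty = L - self.n_paired()
        if not self.segments:
            return 0, n_empty
        n_flank = 0
        for s, g in runs:
            if circular:
                sides = 2
            else:
                sides = (1 if s > 0 else 0) + (1 if s + g < L else 0)
            n_flank += min(g, sides)
        return n_flank, n_empty - n_flank

    def mass(self) -> int:
        return len(self.template.seq) + self._npaired

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"TemplateComplex({self.template!r}, "
                f"{len(self.segments)} segment(s))")


# ---------------------------------------------------------------------------
# Rooms and system state
# ---------------------------------------------------------------------------

@dataclass
class Room:
    """A read-mostly view of one grid room.

    The live state stores precursor and nucleotide counts in flat arrays
    for speed; this view materialises the room-level contract (counts plus
    the entities whose ``room`` field points here).
    """

    coord: tuple[int, int]
    precursor_count: int
    free_nucleotides: dict
    entities: list


class SystemState:
    """Grid state: precursors, free nucleotides, strands and complexes.

    ``precursors`` is a flat ``(N*N,)`` int array; ``nucleotides`` a
    ``(N*N, 4)`` int array with columns in base order A, G, C, U.  Room
    index ``r * N + c`` maps to grid coordinate ``(r, c)``; the toroidal
    neighbours of a room are precomputed in ``neighbours``.
    """

    def __init__(self, params: Parameters, rng: np.random.Generator):
        validate_parameters(params)
        N = params.N
        self.N = N
        n_rooms = N * N
        self.precursors = np.zeros(n_rooms, dtype=np.int64)
        self.nucleotides = np.zeros((n_rooms, 4), dtype=np.int64)
        self.free_strands: list[Strand] = []
        self.complexes: list[TemplateComplex] = []
        self.step = 0
        self.rng = rng
        self.inoculated_mass = 0
        self.initial_mass = int(params.T_NPB)
        self._next_id = 0
        # uniform random placement of the initial precursor endowment
        if params.T_NPB > 0:
            placement = rng.multinomial(params.T_NPB,
                                        np.full(n_rooms, 1.0 / n_rooms))
            self.precursors += placement
        # toroidal neighbour table: up, down, left, right
        idx = np.arange(n_rooms)
        r, c = idx // N, idx % N
        self.neighbours = np.stack([
            ((r - 1) % N) * N + c,
            ((r + 1) % N) * N + c,
            r * N + (c - 1) % N,
            r * N + (c + 1) % N,
        ], axis=1)

    # -- identity ----------------------------------------------------------

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def make_strand(self, seq: str, circular: bool, room: int) -> Strand:
        return Strand(seq, circular, id=self.new_id(), room=room)

    # -- room views --------------------------------------------------------

    def room_index(self, r: int, c: int) -> int:
        return (r % self.N) * self.N + (c % self.N)

    def room(self, r: int, c: int) -> Room:
        idx = self.room_index(r, c)
        nucs = {b: int(self.nucleotides[idx, i]) for i, b in enumerate(BASES)}
        entities: list = [s for s in self.free_strands if s.room == idx]
        entities += [cx for cx in self.complexes if cx.room == idx]
        return Room((idx // self.N, idx % self.N),
                    int(self.precursors[idx]), nucs, entities)

    # -- bookkeeping -------------------------------------------------------

    def all_strands(self) -> Iterable[Strand]:
        """Every strand in the system, including templates and substrates.

        Bound substrates are yielded as transient Strand views carrying the
        segment sequence; census code treats them like any other strand.
        """
        yield from self.free_strands
        for cx in self.complexes:
            yield cx.template
            for seg in cx.segments:
                yield Strand(seg.seq, False, id=-1, room=cx.room)

    def strand_mass(self) -> int:
        m = sum(len(s.seq) for s in self.free_strands)
        for cx in self.complexes:
            m += cx.mass()
        return m

    def target_mass(self) -> int:
        return self.initial_mass + self.inoculated_mass


def total_mass(state) -> int:
    """Total material in nucleotide equivalents.

    Sums precursors, free nucleotides and every strand residue (templates
    and bound substrates included).  Conserved by every event; scenario
    inoculations add to it explicitly.  Accepts the object state or the
    array state of the production engine.
    """
    if hasattr(state, "total_mass"):
        return state.total_mass()
    return int(state.precursors.sum()) + int(state.nucleotides.sum()) \
        + state.strand_mass()
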