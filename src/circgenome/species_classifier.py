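"""Sequence-level recognition: complements, motif containment, ribozyme
function, and the census categories used in the time-series outputs.

A linear RNA containing a characteristic sequence acts as the corresponding
ribozyme only while it is shorter than 1.5x that sequence — beyond that the
redundant residues are assumed to spoil folding of the catalytic domain.
Circular strands never function as ribozymes (the ring is topologically
hindered in folding); their role is the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .model_core import COMPLEMENT, Parameters, Strand, SystemState

#: Functional-length multiplier: a ribozyme chain must be shorter than
#: this multiple of its characteristic sequence to fold and function.
FUNCTIONAL_LENGTH_FACTOR = 1.5


def reverse_complement(seq: str) -> str:
    """Antiparallel Watson-Crick complement (A<->U, G<->C), 5'->3'."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r}") from None


def contains(seq: str, topology: str, motif: str) -> bool:
    """Motif containment; rotation-invariant for circular sequences.

    A circular sequence contains the motif if any rotation does, which is
    equivalent to a substring test on the doubled sequence (the motif must
    not be longer than the ring itself).
    """
    if len(motif) < 1:
        raise ValueError("empty motif")
    if topology == "circular":
        return len(motif) <= len(seq) and motif in seq + seq
    return motif in seq


def max_functional_length(cs: str) -> int:
    """Smallest chain length classified as non-functional: 1.5 x |cs|.

    Function requires ``length < 1.5 * |cs|``; for the 8 nt characteristic
    sequences this bound is 12 nt (a 11-mer may function, a 12-mer cannot).
    """
    return int(FUNCTIONAL_LENGTH_FACTOR * len(cs))


def is_functional_ribozyme(strand: Strand, cs: str) -> bool:
    """True iff the strand can act as the ribozyme defined by ``cs``.

    Requires the linear form (a circular strand cannot fold into the
    functional structure), the characteristic sequence on the sense strand,
    and a chain shorter than 1.5x the characteristic sequence.
    """
    return (not strand.circular
            and len(strand.seq) < FUNCTIONAL_LENGTH_FACTOR * len(cs)
            and cs in strand.seq)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

CATEGORY_NAMES = ("cir_rep", "cir_repcom", "lin_rep", "lin_repcom",
                  "cir_ct", "cir_ctcom", "cir_repnr", "cir_nr",
                  "lin_rep_rib", "lin_nr_rib")


@dataclass
class CategoryCensus:
    """Per-observation species counts, named after the figure-style legend.

    ``counts`` covers every strand in the system, including templates and
    substrates currently engaged in complexes; ``free_counts`` covers only
    unbound strands (the plotted convention is not pinned down, so both are
    recorded).  ``genome_length_histogram`` maps chain length to count over
    the circular strands carrying the REP sequence (the "genomes").
    """

    step: int
    counts: dict = field(default_factory=dict)
    free_counts: dict = field(default_factory=dict)
    genome_length_histogram: dict = field(default_factory=dict)

    def __getattr__(self, name):
        # allow census.cir_rep style access for the documented categories
        if name in CATEGORY_NAMES:
            return self.counts.get(name, 0)
        raise AttributeError(name)


@lru_cache(maxsize=262144)
def _classify(seq: str, circular: bool, cs_rep: str, cs_nr: str,
              cs_ct: str) -> tuple:
    """Category increments for one species, cached per (sequence, topology).

    A strand containing both a characteristic sequence and its reverse
    complement is counted in the sense category only (sense > antisense
    priority, to avoid double counting).
    """
    topo = "circular" if circular else "linear"
    has_rep = contains(seq, topo, cs_rep)
    has_nr = contains(seq, topo, cs_nr)
    has_ct = contains(seq, topo, cs_ct)
    has_repc = contains(seq, topo, reverse_complement(cs_rep))
    has_ctc = contains(seq, topo, reverse_complement(cs_ct))
    cats = []
    if circular:
        if has_rep and has_nr:
            cats.append("cir_repnr")
        elif has_rep:
            cats.append("cir_rep")
        elif has_nr:
            cats.append("cir_nr")
        if has_repc and not has_rep:
            cats.append("cir_repcom")
        if has_ct:
            cats.append("cir_ct")
        elif has_ctc:
            cats.append("cir_ctcom")
        genome_len = len(seq) if has_rep else 0
    else:
        if has_rep:
            cats.append("lin_rep")
        elif has_repc:
            cats.append("lin_repcom")
        n = len(seq)
        if has_rep and n < FUNCTIONAL_LENGTH_FACTOR * len(cs_rep):
            cats.append("lin_rep_rib")
        if has_nr and n < FUNCTIONAL_LENGTH_FACTOR * len(cs_nr):
            cats.append("lin_nr_rib")
        genome_len = 0
    return tuple(cats), genome_len


def classify_categories(seq: str, circular: bool,
                        params: Parameters) -> tuple:
    """Legend categories one strand of this species falls into."""
    cats, _len = _classify(seq, circular, params.CS_REP, params.CS_NR,
                           params.CS_CT)
    return cats


def census(state, params: Parameters) -> CategoryCensus:
    """Count every strand in the system into the legend categories.

    Strands engaged in complexes (templates and bound substrates) are
    included in ``counts``; ``free_counts`` restricts to unbound strands.
    The genome-length histogram covers REP-containing circular strands.
    Works on both the object state (:class:`~.model_core.SystemState`)
    and the array state of the production engine.
    """
    step = state.step if hasattr(state, "step") else state.step_count
    out = CategoryCensus(step=step)
    counts = dict.fromkeys(CATEGORY_NAMES, 0)
    free_counts = dict.fromkeys(CATEGORY_NAMES, 0)
    hist: dict[int, int] = {}
    cs = (params.CS_REP, params.CS_NR, params.CS_CT)

    def tally(seq: str, circular: bool, free: bool) -> None:
        cats, genome_len = _classify(seq, circular, *cs)
        for c in cats:
            counts[c] += 1
            if free:
                free_counts[c] += 1
        if genome_len:
            hist[genome_len] = hist.get(genome_len, 0) + 1

    if hasattr(state, "iter_strands"):
        for seq, circular, _room, engaged in state.iter_strands():
            tally(seq, circular, not engaged)
    else:
        for s in state.free_strands:
            tally(s.seq, s.circular, True)
        for cx in state.complexes:
            tally(cx.template.seq, cx.template.circular, False)
            for seg in cx.segments:
                tally(seg.seq, False, False)

    out.counts = counts
    out.free_counts = free_counts
    out.genome_length_histogram = dict(sorted(hist.items()))
    return out


def modal_genome_length(c: CategoryCensus) -> int:
    """Most common REP-genome chain length (0 if none; ties -> smallest)."""
    if not c.genome_length_histogram:
        return 0
    best = max(c.genome_length_histogram.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]
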