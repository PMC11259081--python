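# Model and methods

## The model

`circgenome` simulates the earliest, precellular stage of the RNA world:
naked RNA molecules evolving on a two-dimensional `N x N` grid of "rooms"
with toroidal wrap-around (no edges).  Each room holds nucleotide
*precursors*, activated free *nucleotides* (A, G, C, U), and RNA strands.
A strand is linear or circular; a template strand together with the
substrate segments base-paired onto it forms a *complex*.  Only molecules
in the same room interact; molecules hop to one of the four neighbouring
rooms by diffusion.  Total material, in nucleotide equivalents, is
strictly conserved: precursors + free nucleotides + every strand residue
(bound or free) always equals the initial endowment `T_NPB` plus whatever
a scenario inoculates.

Sequence carries function.  A linear strand containing a *characteristic
sequence* acts as the corresponding ribozyme, but only while the chain is
shorter than 1.5x that sequence — longer chains carry redundant residues
that are assumed to spoil folding of the catalytic domain; circular
strands never function (the ring is topologically hindered in folding).
Two ribozymes exist: REP, a template-directed ligase (characteristic
sequence `GAGUCUCU`), and NR, a nucleotide synthetase (`UGAUGCAG`).  A
control sequence (`ACGAACUG`) has no function and serves as the
parasite/negative control.  The interesting regime is the labour division
in which circular RNA (a better template: no folding, no vulnerable ends)
carries the genetic role while short linear RNA does the catalysis.

## Events in one Monte Carlo step

Each step applies, in a fixed published order, with all randomness drawn
from one seeded PRNG stream:

1.  precursor -> nucleotide, NR-catalysed attempts first (each consumes
    one of the room's `T_NR x #NR` turnovers, succeeding with `P_NFR`),
    then non-enzymatic attempts at `P_NF` on the untried precursors;
2.  free nucleotide -> precursor decay at `P_ND`;
3.  random intermolecular ligation: each free molecule (a nucleotide
    counts as a length-1 chain) attempts at `P_RL` to join a uniformly
    chosen partner in its room, 3'-to-5';
4.  end-to-end circularization of free linear chains (length >= 3) at
    `P_EL`;
5.  substrate attraction onto templates (below);
6.  template-directed ligation: every junction of adjacently bound
    segments gets one attempt — catalysed at `P_TLR` while the room has
    REP turnovers (`T_REP` per functional REP), non-enzymatically at
    `P_TL` otherwise.  On a circular template, a complement that covers
    every position gets a closure attempt joining its own two ends; on
    success the product is released as a new circular strand;
7.  separation of each bound segment at `P_SP ** sqrt(n)` (`n` = its
    paired positions; more pairs are harder to peel off, softened by the
    square root because self-folding of single chains aids dissociation);
8.  phosphodiester-bond breaking at `P_BB` per single-stranded bond and
    `P_BB ** 1.5` per double-stranded bond (the two parallel bonds break
    synergistically and sever both chains; a broken ring opens into one
    linear chain of the same length, a broken linear chain splits);
9.  terminal-residue decay at linear chain ends: `P_NDE` at a free end,
    `P_NDE ** 1.5` at a blunt paired end where both paired residues decay
    together.  Circular strands, having no ends, are immune — one of the
    two advantages driving circular genomes;
10. movement to a uniform neighbour room: `P_MNP` per precursor, `P_MN`
    per nucleotide, `P_MN / sqrt(m)` per strand or complex of total mass
    `m` (Zimm-type scaling of polymer diffusion).

### Attraction in detail

Every *empty template site* (an unpaired position of any strand or
complex template) is one attraction opportunity per step.  A site
immediately adjacent to a bound segment is *primer-adjacent* and binds at
`P_AT` (circular template) or `P_AT x F_LT` (linear template, which is
the poorer template by the factor `F_LT`); an isolated *de novo* site is
harder by the factor `F_DA` (`P_AT / F_DA`, `P_AT x F_LT / F_DA`).  On a
success, a substrate is chosen uniformly among the room's free
nucleotides and free linear chains short enough to fit in the empty run
around the site; an oligomer's placement start is uniform among the
starts that cover the site.  A nucleotide binds as the Watson-Crick
complement of the template residue — or, with probability `P_FP`, as a
uniformly chosen non-complementary residue; such false pairing is the
model's mutation mechanism.  An oligomer has fixed residues, so `P_FP`
acts per non-complementary position as an acceptance tolerance: each
mismatch must pass an independent `P_FP` draw or the binding fails.
Binding updates the occupancy immediately, so substrates landing next to
a fresh segment in the same step already enjoy the primer effect; the
following ligation phase then sees whole runs of adjacently bound
substrates.  This per-site reading (the published description allows
attraction "at any empty site") is essential quantitatively: with only
one attraction attempt per molecule per step, complement production is an
order of magnitude slower than end decay and no species can spread.

### Ribozyme function

A room's catalytic budget per step is `T_REP x (#functional REP)` ligase
turnovers and `T_NR x (#functional NR)` synthetase turnovers.  Every
linear chain in the room that carries the characteristic sequence and
passes the length rule counts, whether free, templating, or bound in a
duplex — the model conditions function on the chain itself, nothing else.
(The alternative, disabling engaged strands, makes establishment from a
single inoculated molecule impossible, contradicting the intermittent
one-molecule inoculation scenario in which spread does eventually start.)

### Interventions

Scenario interventions rewrite a parameter globally at a scheduled step,
or — for the linear-template factor `F_LT` — for a species scope only
(topology plus required motifs), e.g. "linear strands containing the REP
sequence".  The role-analysis scenarios use this to switch off templating
of the ribozyme (and optionally its complement) mid-run.  Later rules
override earlier ones.

## Parameters

All defaults are carried by `Parameters` (see `model_core.py`); the main
ones, per event-opportunity per step: `P_AT=0.5`, `P_FP=0.001`,
`P_TL=0.01`, `P_TLR=0.9`, `P_SP=0.5`, `P_BB=5e-6`, `P_EL=1e-7`,
`P_RL=1e-7`, `P_NF=0.005`, `P_NFR=0.9`, `P_ND=0.05`, `P_NDE=0.001`,
`P_MN=0.002`, `P_MNP=0.01`; factors `F_DA=5`, `F_LT=0.5`; counts `N=30`,
`T_NPB=1e5`, `T_REP=T_NR=10`.  Validation enforces ranges as hard errors
and reports violations of the qualitative orderings (catalysed >>
uncatalysed, template-directed >> random ligation, end decay < free
decay, nucleotides slower than precursors) as warnings only, because
interventions deliberately break them (e.g. `P_TLR -> 0`).

## Scenarios and presets

Presets reproduce the published experiments: one-gene spread from a bulk
(`fig2a`) or intermittent single-molecule (`fig2b`) inoculation of linear
REP plus control; role analyses switching off linear templating and then
REP catalysis (`fig3`) or stepping the ribozyme's own template factor
down 0.5 -> 0.2 -> 0.1 -> 0 with (`fig4a`) and without (`fig4b`)
circularization; seed variants (`fig5a`-`fig5d`); two-gene circular
genomes (`fig7a`), the noncoding-sequence route to a second gene
(`fig7b`, with `T_NPB=2e5`, `P_BB=2e-5`, `P_FP=0.01`, `P_NDE=0.002`,
`P_NF=0.001` and the noncoding sequence `UGACGCAG` one substitution from
the NR sequence), an NR-first variant (`s1`) and a gene-duplication
variant (`s2`, whose second gene is one substitution from REP; we use
`GAGUCUCA`).  The figure texts do not give the exact steps of the
`fig4a` reductions; we place them at 2e6, 4e6 and 6e6 (the final switch-
off at 6e6 is stated).  "Spread has begun", which stops the periodic
inoculation of `fig2b`, is operationalised as `cir_rep >= 20` on ten
consecutive observations (configurable; the source text states no
criterion).

`*_scaled` variants divide the grid side by 2, the material endowment by
4 (preserving per-room density, hence local kinetics) and step-valued
quantities by 10.  The desk-scale `fig2b_scaled` uses one REP + one
control molecule every 2000 steps over 3e5 steps.  Scaling shrinks
population sizes ~4x, so rare compound events (noncoding insertions,
see below) are proportionally rarer per step; qualitative outcomes are
preserved, waiting times are not.

## Implementation

Two engines implement identical event semantics:

* `event_engine.py` — the object reference implementation (strands,
  segments and complexes as Python objects).  It is the readable
  specification of every event and the substrate for the unit tests,
  handling ~1e3 molecules at ~5 ms/step.
* `fast_engine.py` — the production engine: pooled numpy arrays (2-bit
  base codes in fixed-width rows, occupancy bitmasks, linked segment
  lists) stepped by numba-compiled kernels, ~30x faster.  Binomial event
  counts are drawn by geometric gap-skipping; aggregated draws with
  uniform hit assignment replace per-molecule Bernoullis where that is
  exactly equivalent.  Chains are capped at 40 nt (random ligations that
  would exceed the cap are discarded; chains beyond ~32 nt never arise at
  the simulated scales).  First use in a fresh process compiles the
  kernels (~1-2 minutes), cached thereafter.

`scenario_runner.run` uses the production engine by default
(`engine="reference"` selects the object engine).  Both are exactly
reproducible from `(config, seed)`; their trajectories are not bitwise
comparable with each other because they consume the PRNG stream in
different orders, so the test suite cross-checks them on invariants
(mass conservation, null dynamics, topology rules) and on per-event rate
statistics.

Numerical notes: uniform integer picks in hot kernels use
`floor(u * k)`; probabilities and factors are IEEE doubles throughout;
circular sequences are stored in their lexicographically smallest
rotation so equal rings compare equal; the minimum ring size is 3 nt (a
floor of ours — the source model never creates 1-2 nt rings, which are
chemically implausible).  Inoculated molecules add material on top of
`T_NPB`; the conservation check tracks that addition.

## What the desk-scale runs show — and what they do not

At desk scale (grid 15x15, 2.5e4 material units) the model reproduces,
with default parameters, the qualitative published sequence: inoculated
linear REP spreads by self-replication; circular 8 nt genomes arise by
end-to-end ligation and take the genetic role over (hundreds of rings,
linear ribozymes falling to low copy number); the functionless control
never establishes; switching off REP catalysis prevents establishment;
and without circularization the decline of the ribozyme's own template
capability is fatal.  The emergence and takeover of genomes with a
noncoding insertion (9-12 nt) is a compound rare event whose supply
scales with population size: at quarter population it typically needs
several-fold more steps than the published full-scale cases.  Desk-scale
runs of a few 1e5 steps therefore sometimes, but not always, end with the
longer genome dominant; the acceptance runs report the modal genome
length actually observed.

Problem sizes used by the shipped checks (our desk-scale choices): the
conservation check runs the full 30x30 grid for 1e4 steps; the selection,
catalysis-dependence and circularization-rescue checks run 15x15 /
2.5e4 units for 3-4e4 steps over 2-3 seeds; the insertion check runs
1e5 steps over 2 seeds; the reproduction script's intermittent-
inoculation runs use 8x8 / 7000 units (the same ~110 units per room)
for 4e5 steps over 3 seeds, because establishment from single molecules
is itself rare (~0.6% per inoculated molecule) and longer runs sample
more establishment attempts than extra seeds would.

The generator makes no attempt to model explicit energetics (substrates
are permanently activated), secondary structure (folding enters only via
the 1.5x length rule and the factors `F_LT`, `F_DA`), rolling-circle
replication, or 3D geometry — all outside the model's scope.
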