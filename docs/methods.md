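# Methods

## Scope

parsiphy implements equally weighted maximum parsimony (MP) for mixed
character matrices of the kind used in combined-evidence studies of
golden moles and other mammals: a nuclear gene alignment (DNA), a block
of unordered multistate morphological characters, and a handful of
binary indel presence/absence characters. It covers scoring (Fitch
lengths, per-partition lengths, ACCTRAN branch steps, per-branch
minima), heuristic and exhaustive tree search, strict/majority
consensus, the nonparametric bootstrap, Bremer / partitioned / hidden
branch support, a random-outgroup rooting diagnostic, and a simulator
that generates matrices of this shape on known trees. Likelihood and
Bayesian inference, alignment construction, and ordered/step-matrix
characters are out of scope.

## Scoring model

Characters are unordered and equally weighted (integer per-character
weights are supported and multiply step counts). A cell is a *state
set*: singletons are observations, multi-element sets are
polymorphic/ambiguous cells, the empty set is missing. Gaps in DNA are
treated as missing; IUPAC ambiguity codes expand to state sets.

Two scoring modes govern multi-state cells:

- **uncertainty** (default): standard Fitch — the cell is satisfied by
  any one member state. Implemented as the classic intersect/union
  pass, vectorised across characters with per-character state bitmasks.
- **polymorphism**: every member state must be accounted for. A
  character containing any multi-state cell is scored by a Sankoff
  dynamic program whose states are non-empty subsets of the character's
  state universe, with transformation cost
  `max(#states gained, #states lost)`. This keeps single-state
  substitutions at unit cost, charges a polymorphic terminal one gain
  per extra state, and lets adjacent polymorphic taxa inherit a shared
  polymorphic ancestor instead of paying twice. Polymorphism-mode
  length is never below uncertainty-mode length and equals it when no
  multi-state cells exist (property-tested). The exact cost function
  PAUP uses for its "multiple states treated as polymorphic" setting is
  not documented precisely enough to clone; this subset DP is our
  definition and both modes are always available.

Missing cells never force steps in either mode. Multifurcating trees
are scored exactly by a unit-cost Sankoff pass (a hard-polytomy
length); binary trees take the fast Fitch path. A brute-force
enumerator over all internal-node state assignments (≤ 8 leaves) is the
independent oracle for the uncertainty mode.

### ACCTRAN and branch minima

`branch_steps` roots the tree at a designated taxon (the outgroup; the
first matrix taxon by default), runs the Sankoff down-pass, and
resolves the traceback *toward change* on ties — accelerated
transformation, pulling ambiguous changes rootward. Residual ties pick
the lowest state in the character's sorted state universe, which makes
the reconstruction deterministic. ACCTRAN branch steps sum exactly to
the tree length (tested). An up-down pass also yields each branch's
minimum steps over all most-parsimonious reconstructions; internal
branches with minimum 0 ("no unambiguous optimization") are the ones
removed by the MINBRLEN collapse rule.

A subtlety of that rule: condensed trees are *representations* of sets
of binary optima. When two or more individually-ambiguous branches
collapse at once, the hard-polytomy length of the condensed tree can
exceed the binary optimum even though every branch was individually
collapsible; the binary resolutions still attain the optimum, which is
the sense in which stored optimal trees "score best_length".

## Tree search

Heuristic search is the classic two-phase recipe: greedy stepwise
addition (taxon order randomly permuted per replicate under the seed,
or file order for "as-is"/"simple" addition), then TBR branch swapping
— every edge bisected, the pruned part re-rooted on each of its edges
and reattached on every edge of the remainder — retaining all equally
best trees (optionally capped, PAUP's MAXTREES analogue), with
best-improvement restarts. Optimal trees pooled across replicates are
MINBRLEN-collapsed and de-duplicated by bipartition set. Exhaustive
enumeration (each unrooted binary topology generated exactly once by
sequential insertion) is refused above 9 taxa and serves as the oracle;
the heuristic matches it on all seeded test instances.

Constraints are enforced by discarding candidate trees, never by
penalties: positive constraints filter stepwise-addition candidates by
the induced clade and TBR neighbours by the full clade (with a
prune-and-regraft repair if a replicate's addition phase dead-ends);
converse constraints are checked on complete trees only, since a
partial tree containing the clade can still lose it at the next
insertion. Positive-constrained results protect the enforced branch
from the collapse so the constraint remains visible in the output.

Bootstrap pseudoreplicates resample characters with replacement,
implemented as multiplicative re-weighting (original weights are
preserved); each pseudoreplicate runs one addition sequence ("simple" =
file order by default) plus TBR, and contributes the splits of the
strict consensus of its optimal trees (alternatively each optimal tree
weighted equally). Supports are percentages of pseudoreplicates; a
`reported(min_support=50)` helper mirrors the convention of not
reporting values under 50.

Majority-rule consensus keeps splits whose frequency strictly exceeds
the cutoff (50% default); below-50 cutoffs fall back to greedy
admission by decreasing frequency, skipping incompatible splits.

## Branch support

Bremer support (BS) for a clade is the converse-constrained optimum
minus the unconstrained optimum. Partitioned branch support for
partition *p* is `min_p(without-clade trees) − min_p(with-clade
trees)`, where the with-clade set is the subset of optimal combined
trees containing the clade (positive-constrained search when none do),
and each partition's minimum is taken independently over each tree set
— the convention that makes the published per-partition "with" columns
coherent when multiple optimal trees exist. A `joint_tree` flag reads
all partition lengths off one deterministic representative instead, and
each row records whether all partition minima were attained on a common
tree (when they are not, ΣPBS can drift from BS — the source of
anomalous rows in published tables of this kind). Hidden branch support
is the identity `HBS = BS − Σ PBS`, checked row-by-row on the
published 23-row golden-mole support table shipped as a test fixture.
Constrained searches default to 100 random-addition replicates.

## Random-outgroup rooting diagnostic

Each artificial outgroup is a row of i.i.d. nucleotides drawn at the
stated base composition (defaults A .28 / C .27 / G .22 / T .23 over
913 sites) followed by random binary morphology (145) and indel (8)
characters with p = 0.5 per state — the paper-era defaults; the binary
state probability is an assumption, as the source protocol states only
that the characters were binary. The row is appended to the unchanged
ingroup matrix, a 25-replicate TBR search is run, all optimal trees are
rooted at the artificial taxon, and the ingroup branch it attaches to
is read off: strict agreement across optimal trees first, then a >50%
majority among them, else the replicate counts as unresolved (an
outgroup sitting on a collapsed polytomy never resolves). Tallies are
keyed by the induced ingroup split and always sum, with the unresolved
count, to the number of outgroups. The master seed spawns per-replicate
seed sequences by counter, so any replicate can be reproduced in
isolation. `classify_attachment` maps a split to "at X" (X's stem) or
"within X" relative to named reference clades.

## Simulator

`simulate_matrix` evolves three partitions on one tree: DNA site-i.i.d.
under HKY (stationary frequencies default to the study's GHR estimates
A .2805 / C .265 / G .2218 / T .2327, transition/transversion rate
ratio 2.2696) with optional discrete-gamma rate multipliers (4
equal-probability categories at quantile midpoints, mean normalised to
1; default shape 0.8383); morphology under the k-state Mk model
(default k = 3, giving the 2–4-state mix typical of morphological
matrices); indels as binary Mk. Branch lengths are expected changes per
character. The default tree is Yule-like (uniformly chosen tip splits)
with i.i.d. exponential edge lengths (mean 0.1 by default — moderate
divergence); a user tree's branch annotations are honoured, and the
evolution root is placed at the internal node next to the anchor leaf
so no edge is double-charged. Missing cells are injected uniformly at
`missing_fraction`; polymorphic cells (true state plus one random
alternative — a testing device, not a biological model) at
`polymorphic_fraction`, in the morphology partition only.

What a green simulation test does establish: the pipeline recovers
generating topologies when the data are clean (balanced tree, equal
moderate branch lengths, 2000 sites) and per-split recovery does not
degrade with more data on random trees. What it does not: exponential
branch lengths produce near-zero internal branches (honest polytomies)
and occasional long terminals, so exact-topology recovery is *not*
certain even at 2000 sites — MP's long-branch attraction is real and is
precisely what the random-outgroup diagnostic is for. The simulator
also makes no attempt at indel-process realism, codon structure, or
alignment uncertainty.

The 8-taxon `make_paper_fixture` matrix (3 partitions, missing and
polymorphic cells, small enough for the exhaustive oracle) ships frozen
in the package and is regenerated bit-identically from its seed.

## Numerical and determinism notes

- All randomness flows from numpy Generators seeded by the caller;
  identical seeds give identical searches, bootstraps, surveys and
  matrices (tested end to end).
- Sankoff passes use float64 cost vectors with a large finite sentinel
  (1e9) for forbidden states; all comparisons are on exact small
  integers, rounded once at the end.
- Stepwise-addition ties are broken by seeded draw among equally best
  placements; TBR tie sets are unordered but de-duplicated by canonical
  form, so results are order-independent.
- State universes are sorted strings; every deterministic tie-break
  (ACCTRAN, root state choice) uses that order.
- Character indexing is 1-based in NEXUS text and error messages,
  0-based in the API.

## Known limitations

- Pure-Python TBR: fine for the tested sizes (≤ 10 taxa in seconds; a
  30-taxon, ~1000-character search runs but takes hours at 500
  replicates, far beyond PAUP's C implementation).
- No ordered, Dollo, or irreversible characters; no step matrices; no
  successive weighting.
- NEXUS support targets the mixed-matrix dialect (DATA/CHARACTERS,
  MIXED datatypes, CHARSET, WTSET, TREES); matrix lines must carry
  their taxon label (no unlabelled continuation lines).
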