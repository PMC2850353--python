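# parsiphy

Maximum-parsimony analysis of **mixed character matrices** — a nuclear
gene alignment, unordered multistate morphology, and binary indel
characters in one matrix — of the kind used in combined-evidence
studies of golden moles (Chrysochloridae) and other mammals. It is
aimed at systematists who want the classic PAUP-style MP toolkit as a
scriptable, testable Python library.

## What it computes

For a matrix **X** of characters with state sets per cell (missing
cells free, polymorphic cells either satisfiable by any member state or
charged for every member), and an unrooted tree **T**:

- **Fitch length** `L(T, X) = Σ_c w_c · min #changes of character c on T`,
  with per-partition breakdowns, an exhaustive brute-force oracle, and
  ACCTRAN (accelerated-transformation) branch step counts plus
  per-branch minima (the `COLLAPSE = MINBRLEN` rule).
- **Heuristic MP search**: random-addition stepwise starting trees +
  TBR branch swapping, keeping all equally best trees, MINBRLEN
  collapse and de-duplication; exhaustive enumeration ≤ 9 taxa;
  positive and converse clade constraints; strict and majority-rule
  consensus; nonparametric bootstrap.
- **Branch support**: Bremer support `BS = L(best tree without clade) −
  L(best tree)`, partitioned branch support
  `PBS_p = min_p(without) − min_p(with)`, and hidden branch support
  `HBS = BS − Σ_p PBS_p`, assembled into the classic per-clade table.
- **Random-outgroup rooting diagnostic**: artificial taxa (i.i.d.
  nucleotides at stated base frequencies + random binary characters)
  appended one at a time as the sole outgroup; the ingroup branch each
  one roots the tree on is tallied — a probe for long-branch
  attraction.
- **Simulation**: HKY(+discrete-gamma) DNA, Mk morphology and binary
  indels evolved on known (Yule-like or user) trees, with missing and
  polymorphic cells injected, so the whole pipeline is testable with no
  external data.

The search/bootstrap/support/survey stages are scikit-learn-style
estimators (`MaxParsimonySearch`, `ParsimonyBootstrap`,
`PartitionSupportAnalysis`, `RandomOutgroupSurvey`, … — `fit(X)` then
trailing-underscore attributes); module-level functions wrap them.
A `parsiphy` CLI exposes `pinfo`, `score`, `search`, `bootstrap`,
`consensus`, `support`, `survey`, and `simulate`.

## Worked example

```python
import parsiphy as pp

# a study-shaped matrix simulated on a known tree
cfg = pp.SimulationConfig(n_taxa=8, n_sites=200, n_morphology=30,
                          n_indels=6, branch_length=0.1)
matrix, truth = pp.simulate_matrix(cfg, seed=7)

res = pp.heuristic_search(matrix, n_replicates=10, seed=1)
print(res.best_length, len(res.optimal_trees))
# 238 1
print(res.optimal_trees[0].to_newick())
# (T01,(T02,(((((T03,T04),T06),T07),T08),T05)));
tb, sb = truth.bipartitions(), res.optimal_trees[0].bipartitions()
print("true splits recovered:", len(sb & tb), "of", len(tb))
# true splits recovered: 3 of 5

table = pp.build_support_table(matrix, {"c": ["T03", "T04"]},
                               n_replicates=10, seed=2)
print(table)
#        comb  comb WO  comb BS  GHR  GHR WO  GHR BS  morphology  ...  HBS
# clade                                                           ...
# c       238      246        8  197     205       8          37  ...    1
```

Reading: the shortest tree for the combined matrix needs 238 steps and
recovers 3 of the 5 generating splits (this seed's random tree has two
near-zero internal branches — exactly the regime where parsimony
resolution runs out). Giving up the `(T03,T04)` clade costs 8 extra
steps (its Bremer support): the DNA partition contributes +8, the
morphology partition conflicts (−2), indels add +1, and 1 step of
support is hidden (HBS = 8 − (8 − 2 + 1) = 1) — it emerges only when
the partitions are combined.

## Reproducing published golden-mole numbers

The published combined matrix (the study's supplementary NEXUS file
`gmole-comb-feb10.nex`: GHR alignment + indels + morphology, 30 taxa)
is not redistributable here. If you place it under `data/` at the
repository root, the acceptance tests in
`tests/test_acceptance.py::TestStudyMatrix` recompute the published
tree lengths (957 combined / 600 GHR+indel / 331 morphology), the
211 parsimony-informative GHR sites, the clade-a/b support rows, the
ACCTRAN branch lengths, and the 100-outgroup rooting survey directly
from it; without the file those tests fail with an explanatory message.
The published 23-row support table itself ships as a fixture and its
`HBS = BS − ΣPBS` arithmetic is always verified.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the pipeline end to end on generated data — simulation, heuristic
vs exhaustive search, ACCTRAN, bootstrap, the support table and its HBS
identity, and a small random-outgroup survey — printing a summary of
each stage and writing the (empty) results object to `--out`.

See `docs/methods.md` for the scoring model, search details, tie-break
and determinism rules, and known limitations.
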