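"""Bremer, partitioned, and hidden branch support.

Bremer support (the decay index) for a clade is the extra length the
best trees *lacking* the clade need relative to the unconstrained
optimum, obtained with a converse-constrained search.  Partitioned
branch support (PBS) splits that difference over data partitions: for
partition *p*,

    PBS_p = min_p(length over shortest combined trees lacking the clade)
          - min_p(length over shortest combined trees containing it),

which can be negative when a partition conflicts with the clade.
Hidden branch support, HBS = BS - sum_p PBS_p, is the part of combined
support that emerges only from interaction between partitions.

The "with-clade" baseline is the subset of optimal combined trees that
contain the clade (found by positive-constrained search if no
unconstrained optimum contains it).  Per-partition minima are taken
independently over each tree set by default; ``joint_tree=True`` reads
all partition lengths off a single deterministic representative tree
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitch import fitch_length
from .matrix import CharacterMatrix
from .search import CladeConstraint, MaxParsimonySearch


def _partition_minima(trees, matrix, partitions, joint_tree=False):
    """Per-partition minimum lengths over a set of equally long trees."""
    reports = [fitch_length(t, matrix) for t in trees]
    w = np.asarray(matrix.weights)
    table = {
        p: [int((r.per_character_steps[list(matrix.partition_indices(p))]
                 * w[list(matrix.partition_indices(p))]).sum())
            for r in reports]
        for p in partitions
    }
    if joint_tree:
        # deterministic representative: first tree in newick sort order
        order = sorted(range(len(trees)), key=lambda i: trees[i].to_newick())
        pick = order[0]
        mins = {p: table[p][pick] for p in partitions}
        common = True
    else:
        mins = {p: min(v) for p, v in table.items()}
        # is there one tree attaining every partition's minimum at once?
        common = any(
            all(table[p][i] == mins[p] for p in partitions)
            for i in range(len(trees))
        )
    return mins, common


@dataclass
class CladeSupport:
    """All support numbers for one clade (one Table-style row)."""

    clade: frozenset
    combined_length: int
    combined_without: int
    bremer: int
    partition_with: dict
    partition_without: dict
    pbs: dict
    hbs: int
    mins_on_common_tree: bool = True


class PartitionSupportAnalysis(BaseEstimator):
    """Bremer/PBS/HBS table for a set of labelled clades.

    Parameters
    ----------
    clades : mapping of label -> iterable of taxon names
    partitions : sequence of partition names, optional
        Defaults to every named partition of the matrix.
    n_replicates : int
        Random-addition replicates per constrained search.
    random_state : int, optional
    joint_tree : bool
        Take all partition lengths from one representative tree per
        tree set instead of minimizing each partition independently.

    Attributes
    ----------
    table_ : pandas.DataFrame with the classic column layout
        (comb, comb WO, comb BS, <p>, <p> WO, <p> BS ..., HBS).
    rows_ : dict label -> CladeSupport
    unconstrained_ : SearchResult
    """

    def __init__(self, clades, partitions=None, n_replicates=100,
                 random_state=None, polymorphism_mode="uncertainty",
                 joint_tree=False, max_trees=None):
        self.clades = clades
        self.partitions = partitions
        self.n_replicates = n_replicates
        self.random_state = random_state
        self.polymorphism_mode = polymorphism_mode
        self.joint_tree = joint_tree
        self.max_trees = max_trees

    def fit(self, X: CharacterMatrix, y=None):
        labels = list(self.clades)
        if len(set(labels)) != len(labels):
            raise ValueError("clade labels must be unique")
        parts = list(self.partitions) if self.partitions is not None \
            else [p for p in X.partitions]
        for p in parts:
            X.partition_indices(p)  # existence check
        rng = np.random.default_rng(self.random_state)

        def run(constraint):
            return MaxParsimonySearch(
                n_replicates=self.n_replicates,
                random_state=int(rng.integers(2 ** 31)),
                constraint=constraint,
                polymorphism_mode=self.polymorphism_mode,
                max_trees=self.max_trees,
            ).fit(X).result_

        base = run(None)
        rows: dict[str, CladeSupport] = {}
        for label in labels:
            taxa = frozenset(self.clades[label])
            without = run(CladeConstraint(taxa, converse=True))
            with_trees = [t for t in base.optimal_trees
                          if t.contains_clade(taxa)]
            if not with_trees:
                with_res = run(CladeConstraint(taxa, converse=False))
                with_trees = list(with_res.optimal_trees)
            bs = without.best_length - base.best_length
            mins_with, common_w = _partition_minima(
                with_trees, X, parts, self.joint_tree)
            mins_wo, common_o = _partition_minima(
                without.optimal_trees, X, parts, self.joint_tree)
            pbs = {p: mins_wo[p] - mins_with[p] for p in parts}
            hbs = bs - sum(pbs.values())
            rows[label] = CladeSupport(
                clade=taxa,
                combined_length=base.best_length,
                combined_without=without.best_length,
                bremer=bs,
                partition_with=mins_with,
                partition_without=mins_wo,
                pbs=pbs,
                hbs=hbs,
                mins_on_common_tree=common_w and common_o,
            )

        records = []
        for label in labels:
            r = rows[label]
            rec = {"clade": label, "comb": r.combined_length,
                   "comb WO": r.combined_without, "comb BS": r.bremer}
            for p in parts:
                rec[p] = r.partition_with[p]
                rec[f"{p} WO"] = r.partition_without[p]
                rec[f"{p} BS"] = r.pbs[p]
            rec["HBS"] = r.hbs
            records.append(rec)
        self.table_ = pd.DataFrame.from_records(records).set_index("clade")
        self.rows_ = rows
        self.partitions_ = parts
        self.unconstrained_ = base
        return self


# ----------------------------------------------------------------------
# functional wrappers

def bremer_support(matrix: CharacterMatrix, clade, n_replicates: int = 100,
                   seed=None, best_length: int | None = None,
                   polymorphism_mode: str = "uncertainty"):
    """(length without the clade, Bremer support) for one clade.

    ``best_length`` may supply a precomputed unconstrained optimum to
    avoid re-searching.
    """
    taxa = frozenset(clade.taxa if isinstance(clade, CladeConstraint)
                     else clade)
    rng = np.random.default_rng(seed)
    if best_length is None:
        best_length = MaxParsimonySearch(
            n_replicates=n_replicates,
            random_state=int(rng.integers(2 ** 31)),
            polymorphism_mode=polymorphism_mode,
        ).fit(matrix).best_length_
    without = MaxParsimonySearch(
        n_replicates=n_replicates,
        random_state=int(rng.integers(2 ** 31)),
        constraint=CladeConstraint(taxa, converse=True),
        polymorphism_mode=polymorphism_mode,
    ).fit(matrix).result_
    return without.best_length, without.best_length - best_length


def partitioned_branch_support(matrix: CharacterMatrix, clade,
                               partition: str, with_trees, without_trees,
                               joint_tree: bool = False) -> int:
    """PBS of one partition given the two optimal tree sets."""
    matrix.partition_indices(partition)
    mins_w, _ = _partition_minima(list(with_trees), matrix, [partition],
                                  joint_tree)
    mins_o, _ = _partition_minima(list(without_trees), matrix, [partition],
                                  joint_tree)
    return mins_o[partition] - mins_w[partition]


def hidden_branch_support(bremer: int, pbs) -> int:
    """HBS = combined Bremer support minus the sum of partition PBS."""
    vals = list(pbs.values()) if isinstance(pbs, dict) else list(pbs)
    return int(bremer) - int(sum(vals))


def build_support_table(matrix: CharacterMatrix, clades, partitions=None,
                        n_replicates: int = 100, seed=None,
                        **kwargs) -> pd.DataFrame:
    """Support table (one row per labelled clade); see
    :class:`PartitionSupportAnalysis`."""
    est = PartitionSupportAnalysis(
        clades, partitions=partitions, n_replicates=n_replicates,
        random_state=seed, **kwargs,
    ).fit(matrix)
    return est.table_
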