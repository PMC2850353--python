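from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from parsiphy import (
    CharacterMatrix,
    CladeConstraint,
    PartitionSupportAnalysis,
    bremer_support,
    build_support_table,
    exhaustive_search,
    hidden_branch_support,
    partitioned_branch_support,
)

from conftest import random_standard_matrix

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="module")
def published_table():
    """Branch-support values published for the golden-mole combined
    analysis (23 lettered clades, three data partitions)."""
    return pd.read_csv(DATA / "published_support_values.tsv", sep="\t")


class TestPublishedArithmetic:
    """The support identities must hold row-by-row on the published table."""

    def test_hbs_identity_on_every_row(self, published_table):
        for _, r in published_table.iterrows():
            pbs = {"GHR": r["GHR BS"], "morph": r["morph BS"],
                   "indel": r["indel BS"]}
            assert hidden_branch_support(r["comb BS"], pbs) == r["HBS"], \
                f"row {r['clade']}"

    def test_bremer_is_without_minus_with(self, published_table):
        for _, r in published_table.iterrows():
            assert r["comb BS"] == r["comb WO"] - r["comb"]

    def test_pbs_is_without_minus_with_per_partition(self, published_table):
        for _, r in published_table.iterrows():
            for p in ("GHR", "morph", "indel"):
                assert r[f"{p} BS"] == r[f"{p} WO"] - r[p]


def conflict_matrix():
    """Two partitions built to disagree about the clade {a,b}.

    p1: characters grouping {a,b}; p2: characters grouping {b,c}.
    Kept small (6 taxa) because the tie-rich character set makes the
    equally-best tree plateaus large.
    """
    taxa = list("abcdef")
    cols, parts = [], {"p1": [], "p2": []}
    for _ in range(4):
        parts["p1"].append(len(cols))
        cols.append(["1" if t in "ab" else "0" for t in taxa])
    for _ in range(3):
        parts["p2"].append(len(cols))
        cols.append(["1" if t in "bc" else "0" for t in taxa])
    cells = [[frozenset(col[i]) for col in cols] for i in range(len(taxa))]
    return CharacterMatrix(taxa, cells, ["standard"] * len(cols),
                           partitions=parts)


class TestSyntheticSupport:
    def test_bremer_equals_margin_of_rival_characters(self):
        # 4 characters support {a,b}, 3 support the rival {b,c}: forcing
        # the tree to give up {a,b} costs exactly 4 - 3 = 1 extra step
        m = conflict_matrix()
        base = exhaustive_search(m)
        wo, bs = bremer_support(m, {"a", "b"}, n_replicates=4, seed=0,
                                best_length=base.best_length)
        ex_wo = exhaustive_search(
            m, constraint=CladeConstraint({"a", "b"}, converse=True))
        assert wo == ex_wo.best_length
        assert bs == 1

    def test_conflicting_partitions_have_opposite_pbs_signs(self):
        m = conflict_matrix()
        est = PartitionSupportAnalysis(
            {"ab": ["a", "b"]}, n_replicates=4, random_state=0,
            max_trees=30).fit(m)
        row = est.rows_["ab"]
        assert row.pbs["p1"] > 0 > row.pbs["p2"]
        assert row.hbs == row.bremer - sum(row.pbs.values())

    def test_zero_variation_partition_has_zero_pbs(self):
        m = conflict_matrix()
        cells = [list(r) + [frozenset("0")] * 2 for r in m.cells]
        parts = {k: list(v) for k, v in m.partitions.items()}
        parts["const"] = [7, 8]
        m2 = CharacterMatrix(m.taxa, cells, ["standard"] * 9,
                             partitions=parts)
        est = PartitionSupportAnalysis(
            {"ab": ["a", "b"]}, n_replicates=4, random_state=0,
            max_trees=30).fit(m2)
        assert est.rows_["ab"].pbs["const"] == 0

    def test_single_clade_table_matches_individual_calls(self):
        m = conflict_matrix()
        est = PartitionSupportAnalysis(
            {"bc": ["b", "c"]}, n_replicates=4, random_state=5,
            max_trees=30).fit(m)
        table = est.table_
        assert len(table) == 1
        row = est.rows_["bc"]
        base = est.unconstrained_
        with_trees = [t for t in base.optimal_trees
                      if t.contains_clade({"b", "c"})] or None
        wo, bs = bremer_support(m, {"b", "c"}, n_replicates=4, seed=1,
                                best_length=base.best_length)
        assert (row.combined_without, row.bremer) == (wo, bs)
        assert row.hbs == hidden_branch_support(row.bremer, row.pbs)

    def test_bs_positive_for_strict_consensus_clades(self, rng):
        m = random_standard_matrix(rng, 7, 16)
        base = exhaustive_search(m)
        from parsiphy import consensus
        strict = consensus(list(base.optimal_trees), "strict")
        for clade in strict.tree.bipartitions():
            _, bs = bremer_support(m, clade, n_replicates=4, seed=2,
                                   best_length=base.best_length)
            assert bs >= 1

    def test_unknown_partition_rejected(self):
        m = conflict_matrix()
        with pytest.raises(Exception, match="nope"):
            PartitionSupportAnalysis({"x": ["a", "b"]},
                                     partitions=["nope"],
                                     n_replicates=2).fit(m)


def test_partitioned_branch_support_function():
    m = conflict_matrix()
    base = exhaustive_search(m)
    without = exhaustive_search(
        m, constraint=CladeConstraint({"a", "b"}, converse=True))
    with_trees = [t for t in base.optimal_trees
                  if t.contains_clade({"a", "b"})]
    pbs1 = partitioned_branch_support(m, {"a", "b"}, "p1", with_trees,
                                      without.optimal_trees)
    pbs2 = partitioned_branch_support(m, {"a", "b"}, "p2", with_trees,
                                      without.optimal_trees)
    bs = without.best_length - base.best_length
    assert hidden_branch_support(bs, [pbs1, pbs2]) == bs - pbs1 - pbs2
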