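import numpy as np
import pytest

from parsiphy import (
    CharacterMatrix,
    CladeConstraint,
    ExhaustiveParsimonySearch,
    MaxParsimonySearch,
    PhyloTree,
    bootstrap,
    consensus,
    exhaustive_search,
    heuristic_search,
)
from parsiphy.matrix import MatrixError

from conftest import random_standard_matrix, support_value


def compatible_matrix(tree: PhyloTree, copies=3):
    """One binary character per non-trivial split of the tree."""
    cols = []
    for clade in tree.bipartitions():
        for _ in range(copies):
            cols.append(["1" if t in clade else "0" for t in tree.labels])
    cells = [[frozenset(col[i]) for col in cols]
             for i in range(len(tree.labels))]
    return CharacterMatrix(tree.labels, cells, ["standard"] * len(cols))


class TestExhaustive:
    def test_four_taxa_scores_exactly_three_topologies(self, rng):
        m = random_standard_matrix(rng, 4, 5)
        est = ExhaustiveParsimonySearch().fit(m)
        assert est.n_topologies_scored_ == 3

    def test_refuses_oversized_instances(self, rng):
        m = random_standard_matrix(rng, 10, 4)
        with pytest.raises(ValueError, match="2,027,025"):
            exhaustive_search(m)

    def test_compatible_characters_recover_generating_tree(self):
        tree = PhyloTree.from_label_tuples(
            ((("a", "b"), ("c", "d")), (("e", "f"), ("g", "h"))))
        m = compatible_matrix(tree)
        res = exhaustive_search(m)
        assert len(res.optimal_trees) == 1
        assert res.optimal_trees[0] == tree
        assert res.best_length == len(tree.bipartitions()) * 3


class TestHeuristic:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_optimum_and_tree_set(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 8))
        m = random_standard_matrix(rng, n, int(rng.integers(6, 16)),
                                   n_states=2, p_missing=0.1)
        ex = exhaustive_search(m)
        he = heuristic_search(m, n_replicates=5, seed=seed)
        assert he.best_length == ex.best_length
        assert set(he.optimal_trees) == set(ex.optimal_trees)

    def test_identical_seed_gives_identical_result(self, rng):
        m = random_standard_matrix(rng, 7, 12)
        a = heuristic_search(m, n_replicates=5, seed=99)
        b = heuristic_search(m, n_replicates=5, seed=99)
        assert a.best_length == b.best_length
        assert list(a.optimal_trees) == list(b.optimal_trees)

    def test_fewer_than_four_taxa_trivial_result(self, rng):
        m = random_standard_matrix(rng, 3, 4)
        res = heuristic_search(m, n_replicates=2, seed=0)
        assert res.note and len(res.optimal_trees) == 1

    def test_global_optimum_bounds_heuristic(self, rng):
        m = random_standard_matrix(rng, 6, 10)
        assert exhaustive_search(m).best_length <= \
            heuristic_search(m, n_replicates=1, seed=0).best_length


class TestConstraints:
    def test_converse_search_never_contains_forbidden_clade(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            m = random_standard_matrix(r, 7, 14)
            clade = frozenset({"t1", "t4"})
            res = heuristic_search(
                m, n_replicates=4, seed=seed,
                constraint=CladeConstraint(clade, converse=True))
            assert all(not t.contains_clade(clade)
                       for t in res.optimal_trees)
            assert res.best_length >= \
                heuristic_search(m, n_replicates=4, seed=seed).best_length

    def test_positive_search_only_contains_clade(self, rng):
        m = random_standard_matrix(rng, 7, 14)
        clade = frozenset({"t0", "t5", "t6"})
        res = heuristic_search(m, n_replicates=4, seed=1,
                               constraint=CladeConstraint(clade))
        assert res.optimal_trees
        assert all(t.contains_clade(clade) for t in res.optimal_trees)

    def test_constraint_validation(self, rng):
        m = random_standard_matrix(rng, 5, 4)
        with pytest.raises(MatrixError, match="not in matrix"):
            heuristic_search(m, constraint=CladeConstraint({"zz", "t0"}))
        with pytest.raises(MatrixError, match="non-trivial"):
            heuristic_search(m, constraint=CladeConstraint({"t0"}))

    def test_constrained_matches_constrained_exhaustive(self, rng):
        m = random_standard_matrix(rng, 6, 12)
        con = CladeConstraint({"t2", "t3"}, converse=True)
        assert heuristic_search(m, n_replicates=5, seed=0,
                                constraint=con).best_length == \
            exhaustive_search(m, constraint=con).best_length


class TestConsensus:
    def test_identical_trees_pass_through(self):
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", ("D", "E"))))
        for method in ("strict", "majority"):
            assert consensus([t, t, t], method).tree == t

    def test_conflicting_clade_collapses_to_polytomy(self):
        a = PhyloTree.from_label_tuples(((("A", "B"), "C"), ("D", "E")))
        b = PhyloTree.from_label_tuples(((("A", "C"), "B"), ("D", "E")))
        st = consensus([a, b], "strict").tree
        assert st.contains_clade({"D", "E"})
        assert not st.contains_clade({"A", "B"})
        assert not st.is_binary()

    def test_majority_keeps_two_thirds_clade(self):
        a = PhyloTree.from_label_tuples((("A", "B"), "C", "D"))
        c = PhyloTree.from_label_tuples((("A", "C"), "B", "D"))
        res = consensus([a, a, c], "majority", cutoff=50)
        assert res.tree.contains_clade({"A", "B"})
        (only,) = res.clade_frequencies.values()
        assert only == pytest.approx(100 * 2 / 3)

    def test_mismatched_leaf_sets_rejected(self):
        a = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        b = PhyloTree.from_label_tuples((("A", "B"), ("C", "E")))
        with pytest.raises(ValueError, match="[DE]"):
            consensus([a, b])


class TestBootstrap:
    def test_unanimous_clade_scores_100(self):
        tree = PhyloTree.from_label_tuples(
            ((("a", "b"), "c"), ("d", ("e", "f"))))
        m = compatible_matrix(tree, copies=6)
        sup = bootstrap(m, n_pseudoreplicates=15, seed=4)
        assert support_value(sup, {"a", "b"}, m.taxa) == 100

    def test_uninformative_matrix_supports_nothing(self, rng):
        cells = [[frozenset("0")] * 6 for _ in range(6)]
        m = CharacterMatrix([f"t{i}" for i in range(6)], cells,
                            ["standard"] * 6)
        sup = bootstrap(m, n_pseudoreplicates=8, seed=1)
        assert all(v <= 50 for v in sup.values())

    def test_strong_clade_outranks_all_others(self, rng):
        # 20 identical characters behind one clade, noise elsewhere
        m = random_standard_matrix(rng, 8, 6)
        strong = [[frozenset("1" if i < 3 else "0")] * 20
                  for i in range(8)]
        cells = [list(r) + strong[i] for i, r in enumerate(m.cells)]
        m2 = CharacterMatrix(m.taxa, cells, ["standard"] * (6 + 20))
        sup = bootstrap(m2, n_pseudoreplicates=20, seed=7)
        target = support_value(sup, {"t0", "t1", "t2"}, m2.taxa)
        others = [v for k, v in sup.items()
                  if k not in (frozenset({"t0", "t1", "t2"}),
                               frozenset(m2.taxa) - {"t0", "t1", "t2"})]
        assert target == max(sup.values())
        assert all(target >= v for v in others)

    def test_zero_pseudoreplicates_rejected(self, rng):
        m = random_standard_matrix(rng, 5, 5)
        with pytest.raises(ValueError):
            bootstrap(m, n_pseudoreplicates=0)


def test_estimator_api_is_sklearn_compatible(rng):
    m = random_standard_matrix(rng, 5, 6)
    est = MaxParsimonySearch(n_replicates=2, random_state=0)
    params = est.get_params()
    assert params["n_replicates"] == 2
    est.set_params(n_replicates=3).fit(m)
    assert est.replicates_run_ == 3
    assert est.score() == -est.best_length_
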