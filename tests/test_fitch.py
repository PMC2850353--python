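import numpy as np
import pytest

from parsiphy import (
    CharacterMatrix,
    PhyloTree,
    TreeError,
    branch_steps,
    brute_force_length,
    fitch_length,
    partition_length,
)
from parsiphy.fitch import (
    MatrixEncoding,
    collapse_zero_branches,
    min_branch_lengths,
    tree_length,
)
from parsiphy import _topology as topo

from conftest import phylo_from_int, random_standard_matrix, random_tree


def _matrix(columns, taxa=None, datatypes=None, partitions=None):
    """Columns given as strings ('0011'), '?' = missing, tuple = poly."""
    n = len(columns[0])
    taxa = taxa or [chr(ord("A") + i) for i in range(n)]
    cells = [[] for _ in range(n)]
    for col in columns:
        for i, c in enumerate(col):
            if c == "?":
                cells[i].append(frozenset())
            else:
                cells[i].append(frozenset(c))
    return CharacterMatrix(taxa, cells,
                           datatypes or ["standard"] * len(columns),
                           partitions=partitions)


class TestKnownLengths:
    def test_single_origin_character(self):
        m = _matrix(["0011"])
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_steps == 1

    def test_conflicting_character_needs_two_steps(self):
        m = _matrix(["0101"])
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_steps == 2
        assert brute_force_length(t, m) == 2

    def test_constant_character_is_free(self):
        m = _matrix(["0000", "1111"])
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_steps == 0

    def test_missing_cells_never_force_steps(self):
        m = _matrix(["0?1?"])
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_steps == 1

    def test_weights_multiply_steps(self):
        m = _matrix(["0011", "0101"]).reweight([3, 2])
        t = PhyloTree.from_label_tuples((("A", "B"), ("C", "D")))
        assert fitch_length(t, m).total_steps == 3 * 1 + 2 * 2

    def test_two_leaf_partition_length_counts_mismatches(self):
        m = _matrix(["01", "00", "1?"], partitions={"x": [0, 1], "y": [2]})
        t = PhyloTree.from_label_tuples(("A", "B"))
        assert partition_length(t, m, "x") == 1
        assert partition_length(t, m, "y") == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_fitch_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(4, 7))
            m = random_standard_matrix(rng, n, int(rng.integers(3, 10)),
                                       n_states=3, p_missing=0.15,
                                       p_poly=0.1)
            t = random_tree(rng, m.taxa)
            assert fitch_length(t, m).total_steps == brute_force_length(t, m)

    def test_brute_force_refuses_large_instances(self, rng):
        m = random_standard_matrix(rng, 9, 3)
        t = random_tree(rng, m.taxa)
        with pytest.raises(ValueError, match="8 leaves"):
            brute_force_length(t, m)


class TestInvariants:
    def test_partition_additivity(self, mini_matrix, rng):
        t = random_tree(rng, mini_matrix.taxa)
        rep = fitch_length(t, mini_matrix)
        assert rep.total_steps == sum(rep.per_partition_steps.values())
        assert rep.total_steps == sum(
            partition_length(t, mini_matrix, p)
            for p in mini_matrix.partitions
        )

    def test_adding_characters_never_decreases_length(self, rng):
        m = random_standard_matrix(rng, 6, 10)
        t = random_tree(rng, m.taxa)
        partial = m.select_characters(range(6))
        assert fitch_length(t, m).total_steps >= \
            fitch_length(t, partial).total_steps

    def test_removing_taxon_never_increases_induced_length(self, rng):
        m = random_standard_matrix(rng, 7, 10)
        t = random_tree(rng, m.taxa)
        dropped = sorted(set(m.taxa) - {"t3"})
        t_small = phylo_from_int(
            topo.remove_leaf(t.topology, t.labels.index("t3")),
            list(t.labels))
        assert fitch_length(t_small, m.select_taxa(dropped)).total_steps <= \
            fitch_length(t, m).total_steps

    def test_polymorphism_mode_dominates_uncertainty(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            m = random_standard_matrix(r, 6, 8, n_states=3, p_poly=0.25,
                                       p_missing=0.1)
            t = random_tree(r, m.taxa)
            unc = fitch_length(t, m, "uncertainty").total_steps
            pol = fitch_length(t, m, "polymorphism").total_steps
            assert pol >= unc

    def test_modes_agree_without_multistate_cells(self, rng):
        m = random_standard_matrix(rng, 6, 10, p_poly=0.0, p_missing=0.2)
        t = random_tree(rng, m.taxa)
        assert fitch_length(t, m, "polymorphism").total_steps == \
            fitch_length(t, m, "uncertainty").total_steps


class TestBranchSteps:
    def test_acctran_sums_to_total_and_bounds_minimum(self, rng):
        for seed in range(8):
            r = np.random.default_rng(seed)
            m = random_standard_matrix(r, 6, 12, n_states=3,
                                       p_missing=0.1)
            t = random_tree(r, m.taxa)
            bs = branch_steps(t, m)
            total = fitch_length(t, m).total_steps
            assert sum(bs.acctran.values()) == total == bs.total_steps
            for clade, steps in bs.acctran.items():
                assert bs.minimum[clade] <= steps

    def test_constant_matrix_gives_zero_branches(self, rng):
        m = _matrix(["000000"])
        t = random_tree(rng, m.taxa)
        bs = branch_steps(t, m)
        assert set(bs.acctran.values()) == {0}

    def test_unresolved_tree_rejected(self):
        m = _matrix(["00111"])
        t = PhyloTree.from_label_tuples(("A", "B", "C", ("D", "E")))
        with pytest.raises(TreeError, match="resolve"):
            branch_steps(t, m)

    def test_root_choice_orients_but_conserves_total(self, rng):
        m = random_standard_matrix(rng, 6, 10, n_states=3)
        t = random_tree(rng, m.taxa)
        totals = {
            root: sum(branch_steps(t, m, root=root).acctran.values())
            for root in m.taxa[:3]
        }
        assert len(set(totals.values())) == 1


class TestMinBrLenCollapse:
    def test_zero_minimum_iff_collapsible(self, rng):
        # a branch with an unambiguous change survives, others collapse
        m = _matrix(["001111", "000011"])
        t = PhyloTree.from_label_tuples(
            (("A", "B"), (("C", "D"), ("E", "F"))))
        enc = MatrixEncoding(m.select_taxa(sorted(t.leaf_set)))
        mins = min_branch_lengths(t.topology, enc)
        internal = {k: v for k, v in mins.items() if 1 < len(k) < 5}
        assert any(v >= 1 for v in internal.values())
        collapsed = collapse_zero_branches(t.topology, enc)
        surviving = {s for s in topo.bipartitions(collapsed)}
        assert all(
            mins[k] >= 1 or (frozenset(k) not in surviving
                             and frozenset(range(6)) - k not in surviving)
            for k in internal
        )

    def test_collapse_is_idempotent(self, rng):
        for seed in range(6):
            r = np.random.default_rng(seed)
            m = random_standard_matrix(r, 7, 8, p_missing=0.2)
            t = random_tree(r, m.taxa)
            enc = MatrixEncoding(m)
            once = collapse_zero_branches(t.topology, enc)
            assert collapse_zero_branches(once, enc) == once

    def test_retained_branches_have_positive_minimum(self, rng):
        m = random_standard_matrix(rng, 7, 10)
        t = random_tree(rng, m.taxa)
        enc = MatrixEncoding(m)
        mins = min_branch_lengths(t.topology, enc)
        collapsed = collapse_zero_branches(t.topology, enc)
        for s in topo.bipartitions(collapsed):
            key = s if s in mins else topo.leafset(t.topology) - s
            assert mins[key] >= 1
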