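import numpy as np
import pytest

from parsiphy import (
    SimulationConfig,
    heuristic_search,
    load_mini_fixture,
    make_paper_fixture,
    simulate_matrix,
)
from parsiphy.simulate import (
    discrete_gamma_rates,
    hky_rate_matrix,
    mk_rate_matrix,
)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(n_taxa=3),
        dict(base_frequencies=(0.4, 0.4, 0.4, 0.4)),
        dict(tstv_ratio=0),
        dict(gamma_shape=-1),
        dict(missing_fraction=1.5),
        dict(morphology_states=1),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


class TestRateMachinery:
    def test_hky_rows_sum_to_zero_and_mean_rate_one(self):
        pi = np.array([0.2805, 0.265, 0.2218, 0.2327])
        Q = hky_rate_matrix(pi, 2.2696)
        assert np.allclose(Q.sum(axis=1), 0)
        assert np.isclose(-(pi * np.diag(Q)).sum(), 1.0)
        assert np.allclose(pi @ Q, 0, atol=1e-12)  # stationarity

    def test_mk_matrix_symmetric_unit_rate(self):
        Q = mk_rate_matrix(3)
        assert np.allclose(Q, Q.T)
        assert np.isclose(-np.diag(Q).mean(), 1.0)

    def test_gamma_categories_mean_one_and_increase(self):
        r = discrete_gamma_rates(0.8383, 4)
        assert np.isclose(r.mean(), 1.0)
        assert (np.diff(r) > 0).all()


class TestSimulation:
    def test_zero_branch_lengths_give_constant_matrix(self):
        cfg = SimulationConfig(n_taxa=5, branch_length=0.0, n_sites=40,
                               n_morphology=10, n_indels=2)
        m, _ = simulate_matrix(cfg, seed=0)
        for j in range(m.n_characters):
            col = {c for c in m.column(j)}
            assert len(col) == 1

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_taxa=6, n_sites=50, n_morphology=8,
                               n_indels=2, missing_fraction=0.1,
                               polymorphic_fraction=0.1)
        a, ta = simulate_matrix(cfg, seed=9)
        b, tb = simulate_matrix(cfg, seed=9)
        assert a == b and ta == tb
        c, _ = simulate_matrix(cfg, seed=10)
        assert c != a

    def test_base_frequencies_converge(self):
        cfg = SimulationConfig(n_taxa=4, n_sites=100_000, n_morphology=0,
                               n_indels=0, branch_length=0.05)
        m, _ = simulate_matrix(cfg, seed=3)
        flat = [s for row in m.cells for cell in row for s in cell]
        n = len(flat)
        for base, p in zip("ACGT", cfg.base_frequencies):
            obs = flat.count(base) / n
            assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-3

    def test_missing_fraction_within_binomial_tolerance(self):
        cfg = SimulationConfig(n_taxa=6, n_sites=2000, n_morphology=0,
                               n_indels=0, missing_fraction=0.08)
        m, _ = simulate_matrix(cfg, seed=4)
        cells = [c for row in m.cells for c in row]
        n = len(cells)
        k = sum(1 for c in cells if not c)
        sd = np.sqrt(n * 0.08 * 0.92)
        assert abs(k - 0.08 * n) < 4 * sd

    def test_user_tree_is_respected(self):
        from parsiphy import PhyloTree
        tree = PhyloTree.from_label_tuples(
            (("T01", "T02"), ("T03", ("T04", "T05"))))
        cfg = SimulationConfig(n_taxa=5, tree=tree, n_sites=500,
                               n_morphology=0, n_indels=0,
                               branch_length=0.05)
        m, back = simulate_matrix(cfg, seed=1)
        assert back == tree
        assert set(m.taxa) == tree.leaf_set

    def test_partitions_and_datatypes_layout(self):
        m, _ = simulate_matrix(SimulationConfig(
            n_taxa=5, n_sites=30, n_morphology=10, n_indels=4), seed=0)
        assert set(m.partitions) == {"GHR", "morphology", "indels"}
        assert [m.datatypes[i] for i in m.partitions["GHR"][:1]] == ["dna"]
        assert all(m.datatypes[i] == "binary"
                   for i in m.partitions["indels"])


class TestRecovery:
    def test_search_recovers_known_topology_at_generous_settings(self):
        # balanced tree, equal moderate branch lengths: recovery is
        # essentially certain with 2000 sites
        from parsiphy import PhyloTree
        truth = PhyloTree.from_label_tuples(
            ((("T01", "T02"), ("T03", "T04")),
             (("T05", "T06"), ("T07", "T08"))))
        cfg = SimulationConfig(n_taxa=8, tree=truth, n_sites=2000,
                               n_morphology=0, n_indels=0,
                               branch_length=0.1)
        m, back = simulate_matrix(cfg, seed=12)
        assert back == truth
        res = heuristic_search(m, n_replicates=3, seed=0)
        assert len(res.optimal_trees) == 1
        assert res.optimal_trees[0] == truth

    def test_split_recovery_not_worse_with_more_sites(self):
        # random Yule-like trees have tiny internal branches (honest
        # polytomies) and long terminals (attraction), so recovery is
        # scored per true split, not per whole topology
        from parsiphy import consensus

        def split_recovery(n_sites, seed):
            cfg = SimulationConfig(n_taxa=8, n_sites=n_sites,
                                   n_morphology=0, n_indels=0,
                                   branch_length=0.1)
            m, truth = simulate_matrix(cfg, seed=seed)
            res = heuristic_search(m, n_replicates=3, seed=seed)
            strict = consensus(list(res.optimal_trees), "strict")
            tb = truth.bipartitions()
            return len(strict.tree.bipartitions() & tb) / len(tb)

        seeds = range(10)
        short = sum(split_recovery(200, s) for s in seeds)
        long_ = sum(split_recovery(2000, s) for s in seeds)
        assert long_ >= short


class TestFixture:
    def test_frozen_file_matches_generator(self, mini_matrix):
        assert load_mini_fixture() == mini_matrix
        assert make_paper_fixture() == mini_matrix

    def test_fixture_shape(self, mini_matrix):
        assert mini_matrix.n_taxa == 8
        assert set(mini_matrix.partitions) == {"GHR", "morphology",
                                               "indels"}
        has_missing = any(not c for row in mini_matrix.cells for c in row)
        has_poly = any(len(c) > 1 for row in mini_matrix.cells for c in row)
        assert has_missing and has_poly
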