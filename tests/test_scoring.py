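"""DAG structures and the K2 Dirichlet-multinomial score."""

import numpy as np
import pytest

from bnbmla.scoring import (
    FamilyScoreCache,
    ScoreConfig,
    family_log_score,
    log_marginal_likelihood,
    log_structure_prior,
)
from bnbmla.structure import DAGStructure, is_acyclic

from conftest import make_dataset


class TestStructure:
    def test_empty_graph_acyclic(self):
        assert is_acyclic(DAGStructure.empty(["a", "b", "c"]))

    def test_two_cycle_detected(self):
        s = DAGStructure.from_edges(["a", "b"], [("a", "b"), ("b", "a")])
        assert not is_acyclic(s)

    def test_forward_edges_in_permutation_always_acyclic(self):
        rng = np.random.default_rng(0)
        names = [f"v{i}" for i in range(8)]
        for _ in range(20):
            order = rng.permutation(8)
            edges = []
            for _ in range(12):
                i, j = sorted(rng.choice(8, 2, replace=False))
                edges.append((names[order[i]], names[order[j]]))
            assert is_acyclic(DAGStructure.from_edges(names, edges, max_in_degree=8))

    def test_edge_list_round_trip(self):
        s = DAGStructure.from_edges(["a", "b", "c"], [("a", "c"), ("b", "c")])
        back = DAGStructure.from_edge_list(s.to_edge_list(), ["a", "b", "c"])
        assert back.parent_sets == s.parent_sets

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError, match="own parent"):
            DAGStructure(["a"], [(0,)])


class TestFamilyScore:
    def test_binary_counts_one_one_is_ln_sixth(self):
        ds = make_dataset({"x": [0, 1]}, target="x")
        assert family_log_score(0, (), ds) == pytest.approx(np.log(1 / 6), abs=1e-12)

    def test_zero_observations_score_zero(self):
        ds = make_dataset({"x": np.array([], dtype=int), "y": np.array([], dtype=int)}, target="y",
                          arities={"x": 2, "y": 2})
        assert family_log_score(0, (), ds) == 0.0
        assert family_log_score(1, (0,), ds) == 0.0

    def test_unobserved_parent_configs_contribute_nothing(self):
        # parent always 0: configs 1 and 2 never observed; score equals the
        # parentless score of the child computed on the same data
        ds = make_dataset({"p": [0, 0, 0, 0], "c": [0, 1, 0, 1]}, target="c",
                          arities={"p": 3, "c": 2})
        with_parent = family_log_score(1, (0,), ds)
        without = family_log_score(1, (), ds)
        assert with_parent == pytest.approx(without, abs=1e-12)

    def test_own_parent_rejected(self):
        ds = make_dataset({"x": [0, 1]}, target="x")
        with pytest.raises(ValueError):
            family_log_score(0, (0,), ds)

    def test_cache_agrees_with_recomputation(self):
        rng = np.random.default_rng(1)
        ds = make_dataset(
            {"a": rng.integers(0, 3, 50), "b": rng.integers(0, 2, 50), "y": rng.integers(0, 2, 50)},
            target="y",
        )
        cache = FamilyScoreCache()
        first = family_log_score(2, (0, 1), ds, cache)
        again = family_log_score(2, (0, 1), ds, cache)
        assert cache.hits == 1
        assert again == pytest.approx(first, abs=1e-12)
        assert family_log_score(2, (0, 1), ds) == pytest.approx(first, abs=1e-12)


class TestMarginalLikelihood:
    def test_decomposability_over_independent_nodes(self):
        rng = np.random.default_rng(2)
        ds = make_dataset({"v1": rng.integers(0, 2, 40), "v2": rng.integers(0, 2, 40)}, target="v2")
        empty = DAGStructure.empty(["v1", "v2"])
        total = log_marginal_likelihood(empty, ds)
        assert total == pytest.approx(
            family_log_score(0, (), ds) + family_log_score(1, (), ds), abs=1e-12
        )

    def test_dependence_rewards_the_edge(self, copy_pair_dataset):
        names = copy_pair_dataset.variable_names
        edge = DAGStructure.from_edges(names, [("x", "y")])
        empty = DAGStructure.empty(names)
        assert log_marginal_likelihood(edge, copy_pair_dataset) > log_marginal_likelihood(
            empty, copy_pair_dataset
        )

    def test_family_delta_equals_total_delta(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            {"a": rng.integers(0, 2, 60), "b": rng.integers(0, 3, 60), "y": rng.integers(0, 2, 60)},
            target="y",
        )
        names = ds.variable_names
        g1 = DAGStructure.empty(names)
        g2 = DAGStructure.from_edges(names, [("a", "y")])
        total_delta = log_marginal_likelihood(g2, ds) - log_marginal_likelihood(g1, ds)
        family_delta = family_log_score(2, (0,), ds) - family_log_score(2, (), ds)
        assert total_delta == pytest.approx(family_delta, abs=1e-10)

    def test_relabeling_preserves_total(self):
        rng = np.random.default_rng(4)
        cols = {"a": rng.integers(0, 2, 50), "b": rng.integers(0, 3, 50), "c": rng.integers(0, 2, 50)}
        ds = make_dataset(cols, target="c")
        g = DAGStructure.from_edges(["a", "b", "c"], [("a", "c"), ("b", "c")])
        # permute variable order consistently
        perm = ["c", "a", "b"]
        ds_p = ds.select_variables(perm, target="c")
        g_p = DAGStructure.from_edges(perm, [("a", "c"), ("b", "c")])
        assert log_marginal_likelihood(g, ds) == pytest.approx(
            log_marginal_likelihood(g_p, ds_p), abs=1e-10
        )

    def test_k2_is_not_score_equivalent(self):
        # with asymmetric arities the K2 score of X->Y and Y->X differ on the
        # same data (a real property of the unit-hyperparameter prior)
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 40)
        y = (x > 0).astype(int)
        ds = make_dataset({"x": x, "y": y}, target="y", arities={"x": 3, "y": 2})
        fwd = log_marginal_likelihood(DAGStructure.from_edges(["x", "y"], [("x", "y")]), ds)
        rev = log_marginal_likelihood(DAGStructure.from_edges(["x", "y"], [("y", "x")]), ds)
        assert abs(fwd - rev) > 1e-6


class TestStructurePrior:
    def test_uniform_inside_the_space(self):
        cfg = ScoreConfig()
        g1 = DAGStructure.from_edges(["a", "b", "c"], [("a", "b")])
        g2 = DAGStructure.from_edges(["a", "b", "c"], [("b", "c"), ("a", "c")])
        assert log_structure_prior(g1, cfg) == log_structure_prior(g2, cfg) == 0.0

    def test_in_degree_violation_excluded(self):
        names = [f"v{i}" for i in range(6)]
        g = DAGStructure(names, [(), (), (), (), (), (0, 1, 2, 3, 4)], max_in_degree=5)
        assert log_structure_prior(g, ScoreConfig(max_in_degree=4)) == float("-inf")

    def test_cycle_excluded(self):
        g = DAGStructure.from_edges(["a", "b"], [("a", "b"), ("b", "a")])
        assert log_structure_prior(g, ScoreConfig()) == float("-inf")

    def test_parent_set_size_prior_follows_choose_formula(self):
        # P(G) prop. prod_v 1 / C(n-1, |pa(v)|)
        cfg = ScoreConfig(structure_prior="parent_set_size")
        names = ["a", "b", "c"]
        assert log_structure_prior(DAGStructure.empty(names), cfg) == pytest.approx(0.0)
        one_parent = DAGStructure.from_edges(names, [("a", "c")])
        assert log_structure_prior(one_parent, cfg) == pytest.approx(-np.log(2))
        two_parents = DAGStructure.from_edges(names, [("a", "c"), ("b", "c")])
        assert log_structure_prior(two_parents, cfg) == pytest.approx(-np.log(1))
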