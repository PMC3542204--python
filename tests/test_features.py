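"""Structural-relevance features, Markov blankets and interaction ratios."""

import numpy as np
import pytest

from bnbmla.features import (
    FeatureQuery,
    feature_indicator,
    interaction_ratio,
    markov_blanket,
    markov_blanket_subgraph,
    posterior_from_stack,
    query_indicator_stack,
    subrelevance_posterior,
)
from bnbmla.oracle import enumerate_dags
from bnbmla.structure import DAGStructure


def dag(names, edges):
    return DAGStructure.from_edges(names, edges)


class TestFeatureIndicators:
    def test_v_structure(self):
        g = dag(["X", "Y", "Z"], [("X", "Z"), ("Y", "Z")])
        vals = {
            k: feature_indicator(g, FeatureQuery(kind=k, variables=("X",), target="Y"))
            for k in ("PIR", "DCR", "SR", "A", "TCR", "ConfR")
        }
        assert vals == {"PIR": 1, "DCR": 0, "SR": 1, "A": 0, "TCR": 0, "ConfR": 0}

    def test_mediation_chain(self):
        g = dag(["X", "W", "Y"], [("X", "W"), ("W", "Y")])
        q = lambda k: feature_indicator(g, FeatureQuery(kind=k, variables=("X",), target="Y"))
        assert (q("TCR"), q("DCR"), q("ConfR"), q("A")) == (1, 0, 0, 1)

    def test_common_cause(self):
        g = dag(["W", "X", "Y"], [("W", "X"), ("W", "Y")])
        q = lambda k: feature_indicator(g, FeatureQuery(kind=k, variables=("X",), target="Y"))
        assert (q("ConfR"), q("TCR"), q("DCR"), q("A")) == (1, 0, 0, 1)

    def test_direction_specific_edge(self):
        g = dag(["X", "Y"], [("X", "Y")])
        fwd = feature_indicator(g, FeatureQuery(kind="DCR_directed", variables=("X",), target="Y"))
        g2 = dag(["X", "Y"], [("Y", "X")])
        rev = feature_indicator(g2, FeatureQuery(kind="DCR_directed", variables=("X",), target="Y"))
        assert (fwd, rev) == (1, 0)


class TestMarkovBlanket:
    def test_chain(self):
        g = dag(["X", "Y", "Z"], [("X", "Y"), ("Y", "Z")])
        assert markov_blanket(g, "Y") == {"X", "Z"}

    def test_spouse_included(self):
        g = dag(["X", "Y", "Z"], [("X", "Y"), ("Z", "Y")])
        assert markov_blanket(g, "X") == {"Y", "Z"}

    def test_isolated_target_empty(self):
        g = dag(["X", "Y"], [])
        assert markov_blanket(g, "Y") == set()

    def test_subgraph_definition(self):
        g = dag(["X", "Y", "Z", "W"], [("X", "Y"), ("Y", "Z"), ("W", "Z")])
        mbg = markov_blanket_subgraph(g, "Y")
        assert set(mbg.node_names) == {"X", "Y", "Z", "W"}
        assert set(mbg.edges()) == {("X", "Y"), ("Y", "Z"), ("W", "Z")}

    def test_subgraph_isolated_target(self):
        g = dag(["X", "Y"], [])
        mbg = markov_blanket_subgraph(g, "Y")
        assert mbg.node_names == ["Y"] and mbg.edges() == []

    def test_sr_equals_blanket_membership_on_all_4node_dags(self):
        # definitional equivalence asserted exhaustively over all 543 DAGs
        graphs = enumerate_dags(4, max_in_degree=3)
        names = ["a", "b", "c", "y"]
        sr = query_indicator_stack(graphs, names, FeatureQuery(kind="SR", variables=("a",), target="y"))
        mb = query_indicator_stack(
            graphs, names, FeatureQuery(kind="MBS_membership", variables=("a",), target="y")
        )
        np.testing.assert_array_equal(sr, mb)

    def test_union_bound_holds_per_sample(self):
        graphs = enumerate_dags(4, max_in_degree=3)
        names = ["a", "b", "c", "y"]

        def stack(kind):
            return query_indicator_stack(
                graphs, names, FeatureQuery(kind=kind, variables=("a",), target="y")
            )

        a, dcr, tcr, confr, pir, sr = (
            stack("A"), stack("DCR"), stack("TCR"), stack("ConfR"), stack("PIR"), stack("SR")
        )
        assert np.all(a >= dcr) and np.all(a >= tcr) and np.all(a >= confr)
        assert np.all(sr >= dcr) and np.all(sr >= pir)
        np.testing.assert_array_equal(a, dcr | tcr | confr)
        np.testing.assert_array_equal(sr, dcr | pir)


class TestPosteriors:
    def _uniform_two_node_stack(self):
        # the three DAGs on {a, y} with equal weight
        return enumerate_dags(2, 1), ["a", "y"]

    def test_always_true_feature_posterior_one(self):
        graphs = np.array([np.array([[0, 1], [0, 0]], dtype=bool)] * 10)
        rp = posterior_from_stack(graphs, ["a", "y"], FeatureQuery(kind="DCR", variables=("a",), target="y"))
        assert rp.posterior == 1.0 and rp.mc_standard_error == 0.0

    def test_uniform_prior_adjacency_two_thirds(self):
        graphs, names = self._uniform_two_node_stack()
        rp = posterior_from_stack(graphs, names, FeatureQuery(kind="DCR", variables=("a",), target="y"))
        assert rp.posterior == pytest.approx(2 / 3)

    def test_classification_thresholds(self):
        graphs, names = self._uniform_two_node_stack()
        q = FeatureQuery(kind="DCR", variables=("a",), target="y")
        rp = posterior_from_stack(graphs, names, q)
        assert rp.classification == "moderate"  # 2/3 in [0.5, 0.75]
        rp_high = posterior_from_stack(np.array([graphs[1]] * 4), names, q)
        assert rp_high.classification == "convincing"
        rp_low = posterior_from_stack(np.array([graphs[0]] * 4), names, q)
        assert rp_low.classification == "not relevant"

    def test_sr_singleton_equals_subrelevance(self):
        graphs = enumerate_dags(3, 2)
        names = ["a", "b", "y"]
        sr = posterior_from_stack(graphs, names, FeatureQuery(kind="SR", variables=("a",), target="y"))
        sub = subrelevance_posterior((graphs, names), ("a",), "y")
        assert sr.posterior == pytest.approx(sub)


class TestSubRelevance:
    def test_empty_graph_samples_zero(self):
        graphs = np.zeros((5, 3, 3), dtype=bool)
        assert subrelevance_posterior((graphs, ["a", "b", "y"]), ("a",), "y") == 0.0

    def test_monotone_under_set_containment(self):
        graphs = enumerate_dags(4, 3)
        names = ["a", "b", "c", "y"]
        p1 = subrelevance_posterior((graphs, names), ("a",), "y")
        p2 = subrelevance_posterior((graphs, names), ("a", "b"), "y")
        p3 = subrelevance_posterior((graphs, names), ("a", "b", "c"), "y")
        assert p1 >= p2 >= p3

    def test_matches_explicit_superset_summation(self):
        from itertools import combinations

        graphs = enumerate_dags(4, 3)
        names = ["a", "b", "c", "y"]
        predictors = ["a", "b", "c"]
        target_set = ("a", "b")
        direct = subrelevance_posterior((graphs, names), target_set, "y")
        # explicit: P(MBS = s) summed over every superset s' of the set
        total = 0.0
        for k in range(len(predictors) + 1):
            for combo in combinations(predictors, k):
                if set(target_set) <= set(combo):
                    q = FeatureQuery(kind="MBS_identity", variables=combo, target="y")
                    total += query_indicator_stack(graphs, names, q).mean()
        assert direct == pytest.approx(total, abs=1e-12)

    def test_set_including_target_rejected(self):
        graphs = enumerate_dags(3, 2)
        with pytest.raises(ValueError):
            subrelevance_posterior((graphs, ["a", "b", "y"]), ("a", "y"), "y")


class TestInteractionRatio:
    def test_singleton_ratio_is_exactly_one(self):
        graphs = enumerate_dags(3, 2)
        res = interaction_ratio((graphs, ["a", "b", "y"]), ("a",), "y")
        assert res.ratio == 1.0
        assert res.interaction_ratio == 0.0 and res.redundancy_ratio == 0.0

    def test_zero_denominator_flagged_not_raised(self):
        graphs = np.zeros((5, 3, 3), dtype=bool)
        res = interaction_ratio((graphs, ["a", "b", "y"]), ("a", "b"), "y")
        assert res.undefined

    def test_always_joint_pair_shows_interaction(self):
        # pair present in the blanket only together in half the samples
        g_joint = DAGStructure.from_edges(["a", "b", "y"], [("a", "y"), ("b", "y")]).adjacency()
        g_empty = np.zeros((3, 3), dtype=bool)
        graphs = np.array([g_joint] * 5 + [g_empty] * 5)
        res = interaction_ratio((graphs, ["a", "b", "y"]), ("a", "b"), "y")
        assert res.ratio == pytest.approx(0.5 / 0.25)
        assert res.interaction_ratio == pytest.approx(np.log(2.0))

    def test_exclusive_pair_shows_redundancy(self):
        g_a = DAGStructure.from_edges(["a", "b", "y"], [("a", "y")]).adjacency()
        g_b = DAGStructure.from_edges(["a", "b", "y"], [("b", "y")]).adjacency()
        graphs = np.array([g_a] * 5 + [g_b] * 5)
        res = interaction_ratio((graphs, ["a", "b", "y"]), ("a", "b"), "y")
        assert res.ratio == pytest.approx(0.0)
        assert res.redundancy_ratio == float("inf")
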