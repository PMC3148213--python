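"""Dyad probabilities, likelihoods and expected degrees."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadnet import (
    BipartiteNetwork,
    DirectedNetwork,
    ModelParameters,
    UndirectedNetwork,
    directed_dyad_distribution,
    dyad_log_likelihood,
    dyad_probability,
    expected_degrees,
    network_log_likelihood,
)

unit = st.floats(0.0, 1.0)


class TestDyadProbability:
    @pytest.mark.parametrize("a,b,pi,expected", [
        (1.0, 1.0, 1.0, 1.0),
        (0.0, 0.7, 0.9, 0.0),
        (0.5, 0.5, 0.8, 0.2),
    ])
    def test_product_form(self, a, b, pi, expected):
        assert dyad_probability(a, b, pi) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5), (0.5, 0.5, 2.0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            dyad_probability(*bad)

    @settings(max_examples=50, deadline=None)
    @given(unit, unit, unit, st.floats(0.0, 1.0))
    def test_monotone_in_each_argument(self, a, b, pi, bump):
        base = dyad_probability(a, b, pi)
        assert dyad_probability(min(1, a + bump), b, pi) >= base
        assert dyad_probability(a, min(1, b + bump), pi) >= base
        assert dyad_probability(a, b, min(1, pi + bump)) >= base


class TestDyadLogLikelihood:
    def test_observed_edge(self):
        assert dyad_log_likelihood(1, 0.5) == pytest.approx(np.log(0.5))

    def test_certain_non_edge(self):
        assert dyad_log_likelihood(0, 0.0) == 0.0

    def test_impossible_observation_is_minus_inf(self):
        assert dyad_log_likelihood(1, 0.0) == -np.inf
        assert dyad_log_likelihood(0, 1.0) == -np.inf


class TestNetworkLogLikelihood:
    def test_two_dyads_by_hand(self):
        net = BipartiteNetwork(["a0", "a1"], ["e0"], [(0, 0)])
        params = ModelParameters([1.0, 1.0], [0.5], [0, 0], [[1.0]], event_classes=[0])
        # x = (1, 0), both p = 0.5 → 2 ln 0.5
        assert network_log_likelihood(net, params) == pytest.approx(2 * np.log(0.5))

    def test_empty_network_all_p_zero(self):
        net = BipartiteNetwork(["a0"], ["e0"], [])
        params = ModelParameters([0.0], [0.0], [0], [[0.0]], event_classes=[0])
        assert network_log_likelihood(net, params) == 0.0

    def test_matches_dyadwise_loop(self, random_bipartite_params):
        net, params = random_bipartite_params
        p = params.probability_matrix("bipartite")
        total = 0.0
        for i in range(net.n_actors):
            for j in range(net.n_events):
                x = net.x(i, j)
                total += x * np.log(p[i, j]) + (1 - x) * np.log(1 - p[i, j])
        assert network_log_likelihood(net, params) == pytest.approx(total)

    def test_directed_uses_four_state_distribution(self):
        net = DirectedNetwork(["n0", "n1"], [(0, 1)])
        params = ModelParameters([0.5, 0.5], [0.5, 0.5], [0, 0], [[0.8]],
                                 reciprocity=[[2.0]])
        u = v = 0.5 * 0.5 * 0.8
        dist = directed_dyad_distribution(u, v, 2.0)
        assert network_log_likelihood(net, params) == pytest.approx(np.log(dist[1]))

    def test_dimension_mismatch(self, tiny_bipartite):
        params = ModelParameters([0.5], [0.5, 0.5], [0], [[0.5]], event_classes=[0, 0])
        with pytest.raises(ValueError):
            network_log_likelihood(tiny_bipartite, params)


class TestDirectedDyadDistribution:
    def test_empty_dyad_is_certain(self):
        dist = directed_dyad_distribution(0.0, 0.0, 1.0)
        assert dist == pytest.approx([1, 0, 0, 0])

    def test_independence_at_rho_one(self):
        dist = directed_dyad_distribution(0.5, 0.5, 1.0)
        assert dist == pytest.approx([0.25] * 4)

    def test_reciprocity_reweights_mutual_state(self):
        dist = directed_dyad_distribution(0.5, 0.5, 3.0)
        assert dist[3] / dist[1] == pytest.approx(3.0)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 10.0))
    def test_normalized_and_factorizes_at_rho_one(self, u, v, rho):
        if u == 1.0 and v == 1.0 and rho == 0.0:
            return  # degenerate dyad
        dist = directed_dyad_distribution(u, v, rho)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        indep = directed_dyad_distribution(u, v, 1.0)
        expect = [(1 - u) * (1 - v), u * (1 - v), (1 - u) * v, u * v]
        assert indep == pytest.approx(expect, abs=1e-12)

    def test_degenerate_dyad_raises(self):
        with pytest.raises(ValueError):
            directed_dyad_distribution(1.0, 1.0, 0.0)


class TestExpectedDegrees:
    def test_single_actor_sum(self):
        params = ModelParameters([1.0], [0.2, 0.3], [0], [[1.0]], event_classes=[0, 0])
        actor_deg, event_deg = expected_degrees(params, "bipartite")
        assert actor_deg[0] == pytest.approx(0.5)
        assert event_deg == pytest.approx([0.2, 0.3])

    def test_all_zero(self):
        params = ModelParameters([0.4, 0.1], [0.5], [0, 1], [[0.0], [0.0]],
                                 event_classes=[0])
        actor_deg, event_deg = expected_degrees(params, "bipartite")
        assert np.all(actor_deg == 0) and np.all(event_deg == 0)

    def test_block_model_degrees_constant_within_class(self):
        # without node effects the expected degree is a class property
        params = ModelParameters(
            np.ones(6), np.ones(4), [0, 0, 0, 1, 1, 1],
            [[0.9, 0.2], [0.1, 0.6]], event_classes=[0, 0, 1, 1])
        actor_deg, _ = expected_degrees(params, "bipartite")
        assert np.allclose(actor_deg[:3], actor_deg[0])
        assert np.allclose(actor_deg[3:], actor_deg[3])


class TestContainers:
    def test_bipartite_adjacency_roundtrip(self, tiny_bipartite):
        net2 = BipartiteNetwork.from_adjacency(tiny_bipartite.adjacency())
        assert net2.edges == tiny_bipartite.edges

    def test_no_self_loops(self):
        with pytest.raises(ValueError):
            DirectedNetwork(["a", "b"], [(0, 0)])
        with pytest.raises(ValueError):
            UndirectedNetwork(["a", "b"], [(1, 1)])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            BipartiteNetwork(["a", "a"], ["e"], [])

    def test_directed_degree_vectors(self, small_digraph):
        indeg, outdeg, recdeg = small_digraph.degree_vectors()
        assert list(outdeg) == [1, 2, 1, 0]
        assert list(indeg) == [1, 1, 1, 1]
        assert list(recdeg) == [1, 1, 0, 0]

    def test_dyad_state(self, small_digraph):
        assert small_digraph.dyad_state(0, 1) == (1, 1)
        assert small_digraph.dyad_state(1, 2) == (1, 0)
        assert small_digraph.dyad_state(2, 1) == (0, 1)
        assert small_digraph.dyad_state(0, 3) == (0, 0)

    def test_undirected_symmetry(self):
        net = UndirectedNetwork(["a", "b", "c"], [(2, 0)])
        assert net.x(0, 2) == 1 and net.x(2, 0) == 1

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameters([1.2], [0.5], [0], [[0.5]], event_classes=[0])
        with pytest.raises(ValueError):
            ModelParameters([0.5, 0.5], [0.5, 0.5], [0, 0], [[0.5]],
                            reciprocity=[[-1.0]])
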