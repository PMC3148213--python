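"""NMI, candidate lists and recovery curves."""

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from dyadnet import (
    BipartiteNetwork,
    ModelParameters,
    RankedCandidateList,
    candidate_list,
    normalized_mutual_information,
    recovery_curve,
)


class TestNMI:
    def test_identical_partitions(self):
        assert normalized_mutual_information([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_one_trivial_partition(self):
        assert normalized_mutual_information([0, 0, 0], [0, 1, 2]) == 0.0

    def test_both_trivial(self):
        assert normalized_mutual_information([0, 0], [5, 5]) == 1.0

    def test_hand_computed_contingency(self):
        # X=(0,0,1,1), Y=(0,1,1,1): I ≈ 0.2157 nats, H_x = ln 2,
        # H_y = 0.5623 → 2I/(Hx+Hy) ≈ 0.3437
        got = normalized_mutual_information([0, 0, 1, 1], [0, 1, 1, 1])
        assert got == pytest.approx(0.3437, abs=2e-4)

    def test_matches_sklearn_arithmetic_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 4, 30)
            y = rng.integers(0, 3, 30)
            assert normalized_mutual_information(x, y) == pytest.approx(
                normalized_mutual_info_score(x, y, average_method="arithmetic"),
                abs=1e-9)

    def test_symmetric_and_relabel_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 40)
        y = rng.integers(0, 3, 40)
        assert normalized_mutual_information(x, y) == pytest.approx(
            normalized_mutual_information(y, x))
        relabeled = (x + 1) % 3
        assert normalized_mutual_information(x, y) == pytest.approx(
            normalized_mutual_information(relabeled, y))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            normalized_mutual_information([0, 1], [0, 1, 2])


def _params_2x2(pvals):
    # one actor class, one event class: probabilities = a_i · b_j
    a, b = pvals
    return ModelParameters(a, b, [0, 0], [[1.0]], event_classes=[0, 0])


class TestCandidateList:
    def test_unknown_pairs_excludes_training_edges(self):
        net = BipartiteNetwork(["g0", "g1"], ["d0", "d1"], [(0, 0)])
        params = _params_2x2(([0.5, 0.5], [0.5, 0.5]))
        ranked = candidate_list(params, net, "unknown_pairs")
        assert set(ranked.dyads()) == {(0, 1), (1, 0), (1, 1)}

    def test_known_pairs_scope(self):
        net = BipartiteNetwork(["g0", "g1"], ["d0", "d1"], [(0, 0), (1, 1)])
        params = _params_2x2(([0.9, 0.1], [0.9, 0.1]))
        ranked = candidate_list(params, net, "known_pairs")
        assert ranked.dyads() == [(0, 0), (1, 1)]

    def test_equal_probabilities_row_major(self):
        net = BipartiteNetwork(["g0", "g1"], ["d0", "d1"], [])
        params = _params_2x2(([0.5, 0.5], [0.5, 0.5]))
        ranked = candidate_list(params, net)
        assert ranked.dyads() == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_order_matches_independent_sort(self):
        rng = np.random.default_rng(3)
        net = BipartiteNetwork.from_adjacency(np.zeros((10, 10), int))
        params = ModelParameters(
            rng.uniform(0.1, 1, 10), rng.uniform(0.1, 1, 10),
            rng.integers(0, 2, 10), rng.uniform(0.1, 0.9, (2, 2)),
            event_classes=rng.integers(0, 2, 10))
        ranked = candidate_list(params, net)
        p = params.probability_matrix("bipartite")
        expect = sorted(((i, j) for i in range(10) for j in range(10)),
                        key=lambda d: (-p[d], d[0], d[1]))
        assert ranked.dyads() == expect

    def test_ordering_contract_enforced(self):
        with pytest.raises(ValueError):
            RankedCandidateList([(0, 0, 0.1), (0, 1, 0.9)], "unknown_pairs")
        with pytest.raises(ValueError):
            RankedCandidateList([(0, 0, 0.5), (0, 0, 0.5)], "unknown_pairs")


class TestRecoveryCurve:
    def _ranked(self, n, positives_at):
        entries = [(0, j, 1.0 - j * 0.05) for j in range(n)]
        ranked = RankedCandidateList(entries, "unknown_pairs")
        positives = {(0, j) for j in positives_at}
        return ranked, positives

    def test_perfect_ranking(self):
        ranked, pos = self._ranked(10, [0, 1])
        curve = recovery_curve(ranked, pos, fractions=[0.2, 0.5, 1.0])
        assert curve.recovered == pytest.approx([1.0, 1.0, 1.0])

    def test_positives_last(self):
        ranked, pos = self._ranked(10, [8, 9])
        curve = recovery_curve(ranked, pos, fractions=[0.5, 0.8, 0.9, 1.0])
        assert curve.recovered == pytest.approx([0.0, 0.0, 0.5, 1.0])

    def test_monotone_and_complete_at_one(self):
        rng = np.random.default_rng(0)
        ranked, _ = self._ranked(40, [])
        pos = {(0, int(j)) for j in rng.choice(40, 10, replace=False)}
        curve = recovery_curve(ranked, pos, fractions=np.linspace(0.05, 1, 20))
        assert np.all(np.diff(curve.recovered) >= -1e-12)
        assert curve.recovered[-1] == 1.0

    def test_chance_level_matches_diagonal(self):
        """Random scores recover positives proportionally to list depth."""
        rng = np.random.default_rng(5)
        L, k, reps = 50, 8, 400
        fracs = [0.2, 0.5]
        acc = np.zeros(len(fracs))
        for _ in range(reps):
            order = rng.permutation(L)
            entries = [(0, int(j), 1.0 - rank / L)
                       for rank, j in enumerate(order)]
            ranked = RankedCandidateList(entries, "unknown_pairs")
            pos = {(0, int(j)) for j in rng.choice(L, k, replace=False)}
            acc += recovery_curve(ranked, pos, fractions=fracs).recovered
        acc /= reps
        for f, got in zip(fracs, acc):
            se = np.sqrt(f * (1 - f) / k / reps)
            assert abs(got - f) < 4 * se

    def test_empty_test_set_rejected(self):
        ranked, _ = self._ranked(5, [])
        with pytest.raises(ValueError):
            recovery_curve(ranked, set())

    def test_positives_outside_universe_rejected(self):
        ranked, _ = self._ranked(5, [])
        with pytest.raises(ValueError):
            recovery_curve(ranked, {(3, 3)})
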