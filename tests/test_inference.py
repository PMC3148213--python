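"""Message-passing engine: single messages, sweeps, full runs."""

import numpy as np
import pytest

from dyadnet import (
    BipartiteNetwork,
    CategoricalDistribution,
    GridDistribution,
    InferenceConfig,
    ModelParameters,
    Priors,
    class_map_assignment,
    compute_q_message,
    compute_r_message,
    init_messages,
    normalized_mutual_information,
    plant_bipartite,
    PlantedSpec,
    run_inference,
    update_sweep,
)
from dyadnet.inference import _resolve


GRID5 = np.linspace(0, 1, 5)


def _point(v):
    return GridDistribution.point_mass(GRID5, v)


class TestComputeRMessage:
    def test_edge_with_certain_partner_is_linear_in_activity(self):
        incoming = {"popularity": _point(1.0),
                    "preference": [[_point(1.0)]]}
        r = compute_r_message(1, incoming, "activity", support=GRID5)
        assert r.weights == pytest.approx(GRID5 / GRID5.sum())

    def test_non_edge_mirrors_to_one_minus(self):
        incoming = {"popularity": _point(1.0),
                    "preference": [[_point(1.0)]]}
        r = compute_r_message(0, incoming, "activity", support=GRID5)
        assert r.weights == pytest.approx((1 - GRID5) / (1 - GRID5).sum())

    def test_two_class_mixture_matches_hand_loop(self):
        # two actor classes, distinct point-mass π per class
        pi = [[_point(0.75)], [_point(0.25)]]
        incoming = {
            "activity": _point(0.5),
            "popularity": _point(1.0),
            "actor_class": CategoricalDistribution(np.array([0.5, 0.5])),
            "preference": pi,
        }
        r = compute_r_message(1, incoming, "event_class")
        # hand-coded expectation: Σ_r Q(r) · (a·b·π_r)
        expect = 0.5 * (0.5 * 0.75) + 0.5 * (0.5 * 0.25)
        assert r.weights == pytest.approx([1.0])  # single event class
        # and for an actor-class target each class weight ∝ its own likelihood
        r2 = compute_r_message(1, {
            "activity": _point(0.5), "popularity": _point(1.0),
            "event_class": CategoricalDistribution(np.array([1.0])),
            "preference": pi,
        }, "actor_class")
        lik = np.array([0.5 * 0.75, 0.5 * 0.25])
        assert r2.weights == pytest.approx(lik / lik.sum())
        assert expect == pytest.approx((lik / 2).sum())

    def test_preference_target_mixture_matches_exhaustive_sum(self):
        # brute-force the expected likelihood over all incoming grids
        rng = np.random.default_rng(5)
        wa = rng.dirichlet(np.ones(5))
        wb = rng.dirichlet(np.ones(5))
        wc = rng.dirichlet(np.ones(2))
        wd = rng.dirichlet(np.ones(2))
        pis = rng.dirichlet(np.ones(5), size=(2, 2))
        incoming = {
            "activity": GridDistribution(GRID5, wa),
            "popularity": GridDistribution(GRID5, wb),
            "actor_class": CategoricalDistribution(wc),
            "event_class": CategoricalDistribution(wd),
            "preference": [[GridDistribution(GRID5, pis[r, s]) for s in range(2)]
                           for r in range(2)],
        }
        x = 1
        got = compute_r_message(x, incoming, ("preference", 0, 1), support=GRID5)
        # exhaustive: loop over every grid/class combination
        expect = np.zeros(5)
        for t_idx, t in enumerate(GRID5):
            total = 0.0
            for ia, a in enumerate(GRID5):
                for ib, b in enumerate(GRID5):
                    for r in range(2):
                        for s in range(2):
                            w = wa[ia] * wb[ib] * wc[r] * wd[s]
                            if (r, s) == (0, 1):
                                p = a * b * t
                                total += w * p
                            else:
                                for ip, pv in enumerate(GRID5):
                                    p = a * b * pv
                                    total += w * pis[r, s][ip] * p
            expect[t_idx] = total
        assert got.weights == pytest.approx(expect / expect.sum(), abs=1e-10)


class TestComputeQMessage:
    def test_no_incoming_returns_prior(self):
        prior = GridDistribution.uniform(0, 1, 5)
        q = compute_q_message(prior, [])
        assert q.weights == pytest.approx(prior.weights)

    def test_uniform_prior_times_linear_message(self):
        grid = np.array([0.0, 0.5, 1.0])
        prior = GridDistribution.uniform(0, 1, 3)
        r = GridDistribution.from_unnormalized(grid, grid)  # ∝ a
        q = compute_q_message(prior, [r])
        assert q.weights == pytest.approx([0, 1 / 3, 2 / 3])

    def test_three_messages_match_log_space_product(self):
        rng = np.random.default_rng(7)
        prior = GridDistribution(GRID5, rng.dirichlet(np.ones(5)))
        rs = [GridDistribution(GRID5, rng.dirichlet(np.ones(5))) for _ in range(3)]
        q = compute_q_message(prior, rs)
        brute = prior.weights * rs[0].weights * rs[1].weights * rs[2].weights
        assert q.weights == pytest.approx(brute / brute.sum(), abs=1e-10)


class TestInitMessages:
    def test_zero_noise_equals_priors(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=0)
        _, cfg, priors = _resolve(tiny_bipartite, cfg, None)
        ms = init_messages(tiny_bipartite, cfg, priors, noise=0.0)
        assert np.allclose(ms.q_msgs["a"], 1 / 5)
        assert np.allclose(ms.q_msgs["c"], 1 / 2)

    def test_same_seed_identical(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=11)
        _, cfg, priors = _resolve(tiny_bipartite, cfg, None)
        ms1 = init_messages(tiny_bipartite, cfg, priors)
        ms2 = init_messages(tiny_bipartite, cfg, priors)
        for key in ms1.q_msgs:
            assert np.array_equal(ms1.q_msgs[key], ms2.q_msgs[key])

    def test_different_seed_differs(self, tiny_bipartite):
        c1 = InferenceConfig(q=2, l=2, grid_size=5, seed=1)
        c2 = InferenceConfig(q=2, l=2, grid_size=5, seed=2)
        _, c1, priors = _resolve(tiny_bipartite, c1, None)
        _, c2, _ = _resolve(tiny_bipartite, c2, None)
        ms1 = init_messages(tiny_bipartite, c1, priors)
        ms2 = init_messages(tiny_bipartite, c2, priors)
        assert any(not np.array_equal(ms1.q_msgs[k], ms2.q_msgs[k])
                   for k in ms1.q_msgs)


class TestUpdateSweep:
    def _converged_state(self, net, cfg):
        _, cfg, priors = _resolve(net, cfg, None)
        ms = init_messages(net, cfg, priors)
        for _ in range(cfg.max_sweeps):
            ms, change = update_sweep(ms, net, priors, cfg)
            if change < cfg.tolerance:
                break
        return ms, priors, cfg

    def test_fixed_point_is_stable(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=0, max_sweeps=300)
        ms, priors, cfg = self._converged_state(tiny_bipartite, cfg)
        _, change = update_sweep(ms, tiny_bipartite, priors, cfg)
        assert change < 10 * cfg.tolerance

    def test_full_damping_freezes_messages(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=0, damping=1.0)
        _, cfg, priors = _resolve(tiny_bipartite, cfg, None)
        ms = init_messages(tiny_bipartite, cfg, priors)
        new, change = update_sweep(ms, tiny_bipartite, priors, cfg)
        assert change == 0.0
        for key in ms.q_msgs:
            assert np.array_equal(new.q_msgs[key], ms.q_msgs[key])

    def test_two_sweeps_match_unrolled_single_message_updates(self):
        # 1×2 network, q = l = 1: messages reduce to a, b, π chains that
        # the single-message reference ops can reproduce exactly
        net = BipartiteNetwork(["a0"], ["e0", "e1"], [(0, 0)])
        cfg = InferenceConfig(q=1, l=1, grid_size=5, seed=0, damping=0.0)
        _, cfg, priors = _resolve(net, cfg, None)
        ms = init_messages(net, cfg, priors, noise=0.0)
        ms, _ = update_sweep(ms, net, priors, cfg)
        # R to a at factor (0,0): x=1, partners at uniform prior means
        incoming = {
            "popularity": GridDistribution.uniform(0, 1, 5),
            "preference": [[GridDistribution.uniform(0, 1, 5)]],
        }
        r00 = compute_r_message(1, incoming, "activity", support=GRID5)
        assert ms.r_msgs["a"][0, 0] == pytest.approx(r00.weights, abs=1e-12)
        r01 = compute_r_message(0, incoming, "activity", support=GRID5)
        assert ms.r_msgs["a"][0, 1] == pytest.approx(r01.weights, abs=1e-12)
        # Q from a to factor (0,1) excludes factor (0,1)'s own R-message
        q01 = compute_q_message(GridDistribution.uniform(0, 1, 5), [r00])
        assert ms.q_msgs["a"][0, 1] == pytest.approx(q01.weights, abs=1e-12)


class TestRunInference:
    def test_symmetric_network_gives_uniform_class_posteriors(self):
        x = np.ones((3, 3), dtype=int)
        net = BipartiteNetwork.from_adjacency(x)
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=0)
        s = run_inference(net, cfg)
        assert np.allclose(s.actor_class_probs, 0.5, atol=0.02)
        assert np.allclose(s.event_class_probs, 0.5, atol=0.02)

    def test_planted_recovery_small(self):
        net, params = plant_bipartite(PlantedSpec(n_actors=24, n_events=18, seed=3))
        s = run_inference(net, InferenceConfig(q=2, l=2, grid_size=12, seed=3))
        nmi = normalized_mutual_information(s.actor_class_map(), params.actor_classes)
        assert nmi >= 0.9
        assert s.converged

    def test_model2_clamps_node_effects(self, tiny_bipartite):
        cfg = InferenceConfig(q=1, l=1, grid_size=5, seed=0, node_effects=False)
        s = run_inference(tiny_bipartite, cfg)
        # point mass at a = b = 1
        assert s.activity_mean() == pytest.approx([1.0, 1.0])
        assert s.popularity_mean() == pytest.approx([1.0, 1.0])
        # π then carries the density: 1 edge of 4 dyads
        assert s.preference_mean()[0, 0] == pytest.approx(2 / 6, abs=0.08)

    def test_non_convergence_is_flagged_not_raised(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=0, max_sweeps=1,
                              n_restarts=1)
        s = run_inference(tiny_bipartite, cfg)
        assert s.converged is False
        assert s.sweeps == 1

    def test_determinism(self, tiny_bipartite):
        cfg = InferenceConfig(q=2, l=2, grid_size=5, seed=9)
        s1 = run_inference(tiny_bipartite, cfg)
        s2 = run_inference(tiny_bipartite, cfg)
        assert np.array_equal(s1.actor_class_probs, s2.actor_class_probs)
        assert np.array_equal(s1.preference, s2.preference)

    def test_posterior_rows_normalized(self, random_bipartite_params):
        net, _ = random_bipartite_params
        s = run_inference(net, InferenceConfig(q=2, l=2, grid_size=8, seed=0))
        assert np.allclose(s.actor_class_probs.sum(1), 1.0, atol=1e-9)
        assert np.allclose(s.activity.sum(1), 1.0, atol=1e-9)
        assert np.allclose(s.preference.sum(-1), 1.0, atol=1e-9)


class TestPosteriorContraction:
    def test_preference_posterior_sharpens_with_data(self):
        """More data can only sharpen block-parameter posteriors."""
        sds = []
        for scale in (1, 2, 4):
            net, _ = plant_bipartite(PlantedSpec(
                n_actors=12 * scale, n_events=8 * scale, seed=7))
            s = run_inference(net, InferenceConfig(q=2, l=2, grid_size=10, seed=7))
            sds.append(s.preference_std().mean())
        assert sds[2] < sds[0]


class TestClassMapAssignment:
    def test_argmax_and_tie_rule(self):
        probs = np.array([[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
        assert list(class_map_assignment(probs)) == [0, 0, 1]

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=50)
        got = class_map_assignment(probs)
        expect = [max(range(4), key=lambda k: (row[k], -k)) for row in probs]
        assert list(got) == expect

    def test_rejects_unnormalized_rows(self):
        with pytest.raises(ValueError):
            class_map_assignment(np.array([[0.9, 0.9]]))
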