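import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import oracle_chi_mb_numeric
from arbrl.arbitration import (
    ArbitrationParams,
    ExploitationSpec,
    MBReliabilityState,
    MFReliabilityState,
    agent_trial,
    dynamic_exploitation,
    init_agent_state,
    integrate_values,
    mb_reliability,
    mf_reliability_update,
    softmax_policy,
    transition_rates,
    update_model_choice_prob,
)
from arbrl.fitting import MODEL_SPECS
from arbrl.task import TransitionSetting, sample_transition


class TestMBReliability:
    def test_symmetric_prior_with_empty_history(self):
        state = MBReliabilityState(prior_counts=(1.0, 1.0))
        # Beta(1,1): mean 1/2, variance 1/12 -> chi = 6 for both systems
        assert mb_reliability(state) == pytest.approx(0.5, abs=1e-12)

    def test_four_zero_spe_events(self):
        state = MBReliabilityState(prior_counts=(1.0, 1.0))
        for _ in range(4):
            state.observe(0.0)
        # posterior Beta(5,1) vs Beta(1,5): chi = 42 and 8.4
        assert mb_reliability(state) == pytest.approx(42.0 / 50.4, abs=1e-9)

    def test_swapping_event_classes_mirrors_reliability(self):
        a = MBReliabilityState()
        b = MBReliabilityState()
        events = [0.0, 0.1, 0.9, 0.85, 0.05, 1.0]  # all in [0,.2] or [.8,1]
        for e in events:
            a.observe(e)
            b.observe(1.0 - e)  # flips zero/non-zero classification (eps=0.2)
        assert mb_reliability(a) == pytest.approx(1.0 - mb_reliability(b), abs=1e-12)

    @pytest.mark.parametrize("n_events,seed", [(0, 0), (3, 1), (20, 2), (40, 3)])
    def test_matches_numerical_posterior_integration(self, n_events, seed):
        rng = np.random.default_rng(seed)
        state = MBReliabilityState()
        events = rng.uniform(0, 1, n_events).tolist()
        for e in events:
            state.observe(e)
        expected = oracle_chi_mb_numeric(
            events[-state.window:], state.zero_threshold, state.prior_counts
        )
        assert mb_reliability(state) == pytest.approx(expected, rel=1e-7)

    def test_window_bounds_history(self):
        state = MBReliabilityState(window=20)
        for _ in range(100):
            state.observe(0.9)
        assert len(state.history) == 20


class TestMFReliability:
    def test_half_step_toward_unsigned_rpe(self):
        state = MFReliabilityState(eta=0.5, rpe_max=40.0, omega=10.0)
        state = mf_reliability_update(state, 30.0)
        assert state.omega == pytest.approx(20.0)
        assert state.chi == pytest.approx(0.5)

    def test_full_rate_tracks_rpe_exactly(self):
        state = MFReliabilityState(eta=1.0, rpe_max=40.0, omega=33.0)
        assert mf_reliability_update(state, 7.0).omega == pytest.approx(7.0)

    def test_perfect_prediction_limit(self):
        state = MFReliabilityState(eta=0.3, rpe_max=40.0, omega=0.0)
        for _ in range(10):
            state = mf_reliability_update(state, 0.0)
        assert state.chi == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        eta=st.floats(0.0, 1.0),
        omega0=st.floats(0.0, 40.0),
        rpes=st.lists(st.floats(0.0, 200.0), max_size=30),
    )
    def test_chi_stays_in_unit_interval(self, eta, omega0, rpes):
        state = MFReliabilityState(eta=eta, rpe_max=40.0, omega=omega0)
        for r in rpes:
            state = mf_reliability_update(state, r)
            assert 0.0 <= state.chi <= 1.0


class TestTransitionRatesAndPMB:
    def test_equal_reliabilities_give_equal_rates(self):
        params = ArbitrationParams(a_beta=1.3, a_gamma=1.3)
        beta, gamma = transition_rates(0.37, 0.37, params)
        assert beta == pytest.approx(gamma)

    def test_zero_steepness_flattens_rate(self):
        params = ArbitrationParams(a_beta=1.0, a_gamma=1.0, steepness=0.0)
        for chi in (0.0, 0.4, 1.0):
            beta, _ = transition_rates(chi, 0.5, params)
            assert beta == pytest.approx(0.5)

    def test_rate_arithmetic(self):
        params = ArbitrationParams(a_beta=1.0, a_gamma=1.0, steepness=10.0)
        beta, _ = transition_rates(0.5, 0.5, params)
        assert beta == pytest.approx(1.0 / (1.0 + math.exp(5.0)), abs=1e-9)

    def test_rates_decrease_in_reliability(self):
        params = ArbitrationParams(a_beta=2.0, a_gamma=2.0)
        betas = [transition_rates(chi, 0.5, params)[0] for chi in (0.1, 0.5, 0.9)]
        assert betas[0] > betas[1] > betas[2] > 0

    def test_p_mb_converges_to_rate_ratio(self):
        p = 0.9
        for _ in range(2000):
            p = update_model_choice_prob(p, 0.2, 0.3)
        assert p == pytest.approx(0.2 / 0.5, abs=1e-9)

    def test_equilibrium_is_fixed(self):
        assert update_model_choice_prob(0.5, 0.25, 0.25) == pytest.approx(0.5)

    def test_boundary_jump(self):
        assert update_model_choice_prob(0.0, 1.0, 0.0) == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_p_mb_bounded_over_random_rate_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random()
        for _ in range(10_000):
            p = update_model_choice_prob(p, rng.uniform(0, 2), rng.uniform(0, 2))
            assert 0.0 <= p <= 1.0


class TestValueIntegrationAndExploitation:
    def test_integration_boundaries_and_blend(self):
        q_mb = {("S1", "L"): 10.0, ("S1", "R"): 4.0}
        q_mf = {("S1", "L"): 2.0, ("S1", "R"): 8.0}
        assert integrate_values(q_mb, q_mf, 1.0) == q_mb
        assert integrate_values(q_mb, q_mf, 0.0) == q_mf
        assert integrate_values(q_mb, q_mf, 0.25)[("S1", "L")] == pytest.approx(4.0)

    def test_mismatched_action_sets_rejected(self):
        with pytest.raises(ValueError):
            integrate_values({("S1", "L"): 1.0}, {("S1", "R"): 1.0}, 0.5)

    def test_weighted_variant_boundaries(self):
        spec = ExploitationSpec("weighted", {"tau_mb": 0.4, "tau_mf": 0.1})
        assert dynamic_exploitation(1.0, spec) == pytest.approx(0.4)
        assert dynamic_exploitation(0.0, spec) == pytest.approx(0.1)

    def test_weighted_collapses_to_fixed_when_taus_equal(self):
        spec = ExploitationSpec("weighted", {"tau_mb": 0.27, "tau_mf": 0.27})
        for p in np.linspace(0, 1, 11):
            assert dynamic_exploitation(p, spec) == pytest.approx(0.27, abs=1e-12)

    def test_logistic_midpoint(self):
        spec = ExploitationSpec(
            "logistic", {"c1": 0.1, "c2": 0.5, "c3": 8.0, "c4": 0.6}
        )
        assert dynamic_exploitation(0.6, spec) == pytest.approx(0.3, abs=1e-12)

    def test_logistic_requires_ordered_bounds(self):
        with pytest.raises(ValueError):
            ExploitationSpec("logistic", {"c1": 0.5, "c2": 0.1, "c3": 1.0, "c4": 0.5})

    def test_softmax_uniform_at_zero_tau(self):
        assert softmax_policy([3.0, -1.0], 0.0) == pytest.approx([0.5, 0.5])

    def test_softmax_arithmetic(self):
        p = softmax_policy([1.0, 0.0], 1.0)
        e = math.e
        assert p == pytest.approx([e / (1 + e), 1 / (1 + e)], abs=1e-9)

    def test_softmax_greedy_limit_and_stability(self):
        p = softmax_policy([1000.0, 999.0], 500.0)  # would overflow naively
        assert p[0] == pytest.approx(1.0, abs=1e-12)
        assert p.sum() == pytest.approx(1.0)


class TestAgentTrial:
    @staticmethod
    def _run(seed, t3_params, graph, state=None):
        spec = MODEL_SPECS["Arb_a_t3"]
        params = spec.agent_params(t3_params)
        state = state or init_agent_state(params, graph)
        rng = np.random.default_rng(seed)
        setting = TransitionSetting()
        sample = lambda s, a: sample_transition(s, a, "low", rng, graph, setting)
        return agent_trial(
            state, params, graph, "flexible", "low", sample, rng=rng
        )

    def test_identical_seeds_give_identical_trajectories(self, t3_params, graph):
        (a_actions, _, a_lat) = self._run(123, t3_params, graph)
        (b_actions, _, b_lat) = self._run(123, t3_params, graph)
        assert a_actions == b_actions
        assert a_lat == b_lat

    def test_latent_record_structure(self, t3_params, graph):
        actions, _, lat = self._run(5, t3_params, graph)
        assert len(actions) == 2
        assert len(lat["spe"]) == 2
        assert len(lat["rpe"]) == 2
        assert len(lat["action_probs"]) == 2
        assert 0.0 <= lat["p_mb"] <= 1.0
        for probs in lat["action_probs"]:
            assert sum(probs) == pytest.approx(1.0)

    def test_pinned_mb_agent_maximizes_known_reward(self, graph):
        """With P_MB pinned at 1, kappa = 1 and near-greedy tau, choices
        maximize true expected reward once transitions have been seen."""
        spec = MODEL_SPECS["Arb_a_t3"]
        params = spec.agent_params(
            {
                "alpha_mb": 1.0, "alpha_mf": 0.0, "eta": 0.0,
                "A_beta": 0.0, "A_gamma": 0.0,  # freezes P_MB at its start
                "tau_mb": 50.0, "tau_mf": 50.0,
            }
        )
        from arbrl.arbitration import ArbConfig

        config = ArbConfig(p_mb_init=1.0)
        state = init_agent_state(params, graph, config)
        rng = np.random.default_rng(1)
        setting = TransitionSetting({"low": (1.0, 0.0)})  # deterministic world
        sample = lambda s, a: sample_transition(s, a, "low", rng, graph, setting)
        # expose every (state, action); with kappa = 1 the last stage-1
        # observation must match the deterministic environment (L -> S2,
        # R -> S4), so the off-path states are visited first
        exposures = [("L", "S3"), ("R", "S5"), ("L", "S2"), ("R", "S4")]
        for a1, s2 in exposures:
            for a2 in ("L", "R"):
                out = graph.successors(s2, a2)[0]
                agent_trial(
                    state, params, graph, "flexible", "low", sample,
                    forced=(a1, s2, a2, out), config=config,
                )
        # deterministic transitions: best path is the max-value coin (red, 40)
        actions, _, lat = agent_trial(
            state, params, graph, "flexible", "low", sample, rng=rng, config=config
        )
        assert lat["reward"] == pytest.approx(40.0)
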