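import numpy as np
import pandas as pd
import pytest

from arbrl.measures import (
    IdealAgent,
    accumulated_reward,
    calibration_curve,
    choice_consistency,
    choice_optimality,
    condition_breakdown,
    correlate_with_score,
)
from arbrl.task import FLEXIBLE, TransitionSetting, build_task_graph, goal_reward, specific
from conftest import make_log


@pytest.fixture(scope="module")
def ideal():
    return IdealAgent()


class TestIdealAgent:
    def test_policy_matches_brute_force_expectations(self, ideal, graph):
        """Greedy policy recomputed here directly from path expectations."""
        for goal in (FLEXIBLE, specific("red"), specific("blue"), specific("yellow")):
            for unc, p in (("low", 0.9), ("high", 0.5)):
                w = (p, 1 - p)
                q2 = {
                    s: [
                        sum(
                            wi * goal_reward(sp, goal, graph)
                            for wi, sp in zip(w, graph.successors(s, a))
                        )
                        for a in ("L", "R")
                    ]
                    for s in graph.second_stage_states
                }
                q1 = [
                    sum(
                        wi * max(q2[sp])
                        for wi, sp in zip(w, graph.successors("S1", a))
                    )
                    for a in ("L", "R")
                ]
                probs = [
                    ideal.policy_prob("S1", a, goal, unc) for a in ("L", "R")
                ]
                assert sum(probs) == pytest.approx(1.0)
                if abs(q1[0] - q1[1]) > 1e-9:
                    assert probs[int(q1[1] > q1[0])] == 1.0
                else:
                    assert probs == pytest.approx([0.5, 0.5])

    def test_high_uncertainty_ties_second_stage(self, ideal, graph):
        # p = 0.5: both actions of a second-stage state share the same
        # outcome pair, so their expectations are equal -> uniform policy
        for s in graph.second_stage_states:
            assert ideal.policy_prob(s, "L", FLEXIBLE, "high") == pytest.approx(0.5)

    def test_stage1_choices_differ_across_goals_at_low_uncertainty(self, ideal):
        best = {}
        for goal in (FLEXIBLE, specific("red"), specific("blue"), specific("yellow")):
            q1, _ = ideal.q_values(goal, "low")
            assert abs(q1[0] - q1[1]) > 1e-9  # no stage-1 tie in any goal
            best[goal] = "LR"[int(q1[1] > q1[0])]
        assert set(best.values()) == {"L", "R"}


class TestAccumulatedReward:
    def test_sum_over_main_trials(self):
        log = make_log(
            [{"reward": 40.0}, {"reward": 0.0}, {"reward": 10.0},
             {"reward": 99.0, "is_pretraining": True, "session": 0}]
        )
        assert accumulated_reward(log) == pytest.approx(50.0)

    def test_zero_rewards(self):
        assert accumulated_reward(make_log([{"reward": 0.0}] * 4)) == 0.0

    def test_consistent_with_goal_reward_recomputation(self, sim_log, graph):
        recomputed = sum(
            goal_reward(t.s_outcome, t.goal, graph)
            for t in sim_log.itertuples()
            if not t.is_pretraining
        )
        assert accumulated_reward(sim_log) == pytest.approx(recomputed)

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            accumulated_reward(pd.DataFrame(columns=["is_pretraining", "reward"]))


class TestChoiceOptimality:
    def test_always_greedy_scores_one(self, ideal):
        # specific(red), low uncertainty: stage 1 best is L; at S2 best is L
        log = make_log(
            [{"goal": specific("red"), "uncertainty": "low",
              "a1": "L", "s2": "S2", "a2": "L", "s_outcome": "O1"}] * 6
        )
        assert choice_optimality(log, ideal) == pytest.approx(1.0)

    def test_indifferent_ideal_gives_half(self):
        # symmetric coin values under a flexible goal: ties everywhere
        g = build_task_graph(
            {"coin_values": {"red": 10.0}, "outcome_colors": ["red"] * 8}
        )
        ideal = IdealAgent(graph=g)
        log = make_log(
            [{"goal": FLEXIBLE, "uncertainty": "low",
              "a1": "R", "s2": "S4", "a2": "L", "s_outcome": "O5"}] * 5
        )
        assert choice_optimality(log, ideal) == pytest.approx(0.5)

    def test_three_greedy_of_four(self, ideal):
        rows = [
            {"goal": specific("red"), "uncertainty": "low",
             "a1": "L", "s2": "S2", "a2": "L", "s_outcome": "O1"},
            {"goal": specific("red"), "uncertainty": "low",
             "a1": "L", "s2": "S2", "a2": "R", "s_outcome": "O2"},
        ]
        log = make_log(rows)
        # decisions: S1(L good), S2(L good), S1(L good), S2(R bad) -> 3/4
        assert choice_optimality(log, ideal) == pytest.approx(0.75)

    def test_random_agent_converges_to_half(self, ideal):
        rng = np.random.default_rng(0)
        graph = build_task_graph()
        rows = []
        for _ in range(600):
            a1 = "LR"[rng.integers(2)]
            s2 = graph.successors("S1", a1)[rng.integers(2)]
            a2 = "LR"[rng.integers(2)]
            out = graph.successors(s2, a2)[rng.integers(2)]
            rows.append(
                {"goal": specific("red"), "uncertainty": "low",
                 "a1": a1, "s2": s2, "a2": a2, "s_outcome": out, "reward": 0.0}
            )
        opt = choice_optimality(make_log(rows), ideal)
        assert opt == pytest.approx(0.5, abs=0.05)


class TestChoiceConsistency:
    def test_two_thirds_example(self):
        log = make_log([{"a1": a} for a in ("L", "L", "R", "R")])
        assert choice_consistency(log) == pytest.approx(2.0 / 3.0)

    def test_constant_choices(self):
        assert choice_consistency(make_log([{"a1": "L"}] * 10)) == 1.0

    def test_strict_alternation(self):
        log = make_log([{"a1": "LR"[i % 2]} for i in range(10)])
        assert choice_consistency(log) == 0.0

    def test_no_carry_over_across_sessions(self):
        rows = [{"a1": "L", "session": 1}, {"a1": "L", "session": 1},
                {"a1": "R", "session": 2}, {"a1": "R", "session": 2}]
        log = make_log(rows)
        # the L->R flip straddles the session boundary and is not counted
        assert choice_consistency(log) == 1.0

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            choice_consistency(make_log([{"a1": "L"}]))


class TestCalibrationCurve:
    def test_simulated_calibrated_agent(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 4000)
        chose = (rng.random(4000) < p).astype(float)
        table = calibration_curve(p, chose, n_bins=10)
        occupied = table[table["count"] > 30]
        for row in occupied.itertuples():
            se = np.sqrt(row.mean_predicted * (1 - row.mean_predicted) / row.count)
            assert abs(row.prop_right - row.mean_predicted) < 4 * se + 1e-9

    def test_single_occupied_bin_at_half(self):
        table = calibration_curve([0.5] * 200, [0, 1] * 100, n_bins=10)
        occupied = table[table["count"] > 0]
        assert len(occupied) == 1
        assert occupied["prop_right"].iloc[0] == pytest.approx(0.5)

    def test_deterministic_agent_top_bin(self):
        table = calibration_curve([1.0] * 50, [1.0] * 50, n_bins=5)
        top = table.iloc[-1]
        assert top["count"] == 50
        assert top["prop_right"] == pytest.approx(1.0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [1.0], n_bins=1)


def _cells(values_by_cell, n_per_cell, noise_rng=None):
    rows = []
    for (g, u), v in values_by_cell.items():
        for _ in range(n_per_cell):
            x = v if noise_rng is None else v + noise_rng.normal(0, 0.1)
            rows.append({"goal_kind": g, "uncertainty": u, "score": x})
    return pd.DataFrame(rows)


class TestConditionBreakdown:
    def test_identical_values_give_zero_f(self):
        df = _cells(
            {(g, u): 0.7 for g in ("flexible", "specific") for u in ("low", "high")},
            5,
        )
        out = condition_breakdown(df)
        assert all(abs(f) < 1e-9 for f in out["F"].values())

    def test_pure_goal_contrast(self):
        rng = np.random.default_rng(1)
        df = _cells(
            {("flexible", "low"): 1.0, ("flexible", "high"): 1.0,
             ("specific", "low"): 0.0, ("specific", "high"): 0.0},
            30, rng,
        )
        out = condition_breakdown(df)
        assert out["F"]["goal"] > 50
        assert out["F"]["interaction"] < 5
        assert out["F"]["goal"] > 10 * out["F"]["uncertainty"]

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(2)
        df = _cells(
            {("flexible", "low"): 0.8, ("flexible", "high"): 0.6,
             ("specific", "low"): 0.5, ("specific", "high"): 0.55},
            20, rng,
        )
        out = condition_breakdown(df)
        # balanced design: classical two-way decomposition by hand
        y = df["score"].to_numpy()
        g = (df["goal_kind"] == "flexible").to_numpy()
        u = (df["uncertainty"] == "low").to_numpy()
        grand = y.mean()
        n = len(y)
        ss_g = sum(
            (y[m].mean() - grand) ** 2 * m.sum() for m in (g, ~g)
        )
        ss_u = sum(
            (y[m].mean() - grand) ** 2 * m.sum() for m in (u, ~u)
        )
        ss_cells = sum(
            (y[m].mean() - grand) ** 2 * m.sum()
            for m in (g & u, g & ~u, ~g & u, ~g & ~u)
        )
        ss_int = ss_cells - ss_g - ss_u
        ss_res = sum(
            ((y[m] - y[m].mean()) ** 2).sum()
            for m in (g & u, g & ~u, ~g & u, ~g & ~u)
        )
        ms_res = ss_res / (n - 4)
        assert out["F"]["goal"] == pytest.approx(ss_g / ms_res, rel=1e-6)
        assert out["F"]["uncertainty"] == pytest.approx(ss_u / ms_res, rel=1e-6)
        assert out["F"]["interaction"] == pytest.approx(ss_int / ms_res, rel=1e-6)

    def test_empty_cell_rejected(self):
        df = _cells({("flexible", "low"): 1.0, ("specific", "high"): 0.0}, 5)
        with pytest.raises(ValueError):
            condition_breakdown(df)


class TestCorrelateWithScore:
    def test_identity_is_perfect(self):
        r, p = correlate_with_score([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1, _ = correlate_with_score(x, y, kind="spearman")
        r2, _ = correlate_with_score(np.exp(x), y ** 3, kind="spearman")
        assert r1 == pytest.approx(r2)

    def test_hand_computed_rank_correlation(self):
        # ranks of x: 1,2,3,4,5; ranks of y: 2,1,4,3,5; sum d^2 = 4
        x = [10.0, 20.0, 30.0, 40.0, 50.0]
        y = [0.2, 0.1, 1.5, 0.9, 3.0]
        r, _ = correlate_with_score(x, y, kind="spearman")
        assert r == pytest.approx(1 - 6 * 4 / (5 * 24))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_score([1.0] * 5, [1, 2, 3, 4, 5])
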