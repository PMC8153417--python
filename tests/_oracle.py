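"""Independent straight-line oracles used to cross-check the package.

Everything here is written from the model definitions alone, without
reusing any code path from ``arbrl``: plain dictionaries, explicit loops,
and textbook formulas.  The likelihood oracle replays a trial log
decision by decision; the planning oracle enumerates the two-step path
tree; the reliability oracle integrates the Beta posterior numerically.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

ACTS = ("L", "R")


def oracle_goal_reward(outcome, goal, outcome_colors, coin_values):
    v = coin_values[outcome_colors[outcome]]
    if goal == "flexible":
        return v
    color = goal.split(":", 1)[1]
    return v if outcome_colors[outcome] == color else 0.0


def oracle_plan_q1(T, graph_succ, outcome_colors, coin_values, goal, second_states):
    """First-stage Q values by explicit enumeration of all 2-step paths."""
    q1 = {}
    for a1 in ACTS:
        total = 0.0
        for s2 in graph_succ[("S1", a1)]:
            p_s2 = T[("S1", a1)][s2]
            # best second-stage action at s2, from its own path expectations
            best = -math.inf
            for a2 in ACTS:
                v = 0.0
                for o in graph_succ[(s2, a2)]:
                    v += T[(s2, a2)][o] * oracle_goal_reward(
                        o, goal, outcome_colors, coin_values
                    )
                best = max(best, v)
            total += p_s2 * best
        q1[a1] = total
    return q1


def oracle_chi_mb_numeric(spe_history, eps, prior):
    """chi_MB with posterior moments obtained by numerical integration."""
    a0, b0 = prior
    n0 = sum(1 for s in spe_history if s <= eps)
    n1 = len(spe_history) - n0

    def moments(a, b):
        norm, _ = integrate.quad(
            lambda x: x ** (a - 1) * (1 - x) ** (b - 1), 0, 1
        )
        m1, _ = integrate.quad(
            lambda x: x * x ** (a - 1) * (1 - x) ** (b - 1) / norm, 0, 1
        )
        m2, _ = integrate.quad(
            lambda x: x * x * x ** (a - 1) * (1 - x) ** (b - 1) / norm, 0, 1
        )
        return m1, m2 - m1 * m1

    mean0, var0 = moments(a0 + n0, b0 + n1)
    mean1, var1 = moments(a0 + n1, b0 + n0)
    chi0 = mean0 / var0
    chi1 = mean1 / var1
    return chi0 / (chi0 + chi1)


def oracle_session_nll(
    log_rows,
    params,
    variant,
    graph_succ,
    outcome_colors,
    coin_values,
    second_states,
    eps=0.2,
    window=20,
    prior=(1.0, 1.0),
    rpe_max=40.0,
    big_b=6.0,
    p_mb0=0.5,
    prob_floor=1e-12,
):
    """Negative log-likelihood by direct replay of a list of trial dicts.

    ``params`` holds alpha_mb, alpha_mf, eta, A_beta, A_gamma and the
    exploitation parameters of the given variant.  Pre-training rows only
    train the transition model and the SPE history.
    """
    T = {key: {s: 1.0 / len(succ) for s in succ} for key, succ in graph_succ.items()}
    qmf = {(s, a): 0.0 for s in ("S1",) + tuple(second_states) for a in ACTS}
    spes: list[float] = []
    omega = 0.0
    p_mb = p_mb0
    nll = 0.0

    def tau_of(p):
        if variant == "fixed":
            return params["tau"]
        if variant == "logistic":
            return params["c1"] + (params["c2"] - params["c1"]) / (
                1.0 + math.exp(-params["c3"] * (p - params["c4"]))
            )
        if variant == "linear":
            return p * params["c"]
        return p * params["tau_mb"] + (1.0 - p) * params["tau_mf"]

    def chi_mb_now():
        a0, b0 = prior
        recent = spes[-window:]
        n0 = sum(1 for s in recent if s <= eps)
        n1 = len(recent) - n0
        # mean/variance of Beta(a, b), spelled out
        def chi(a, b):
            mean = a / (a + b)
            var = a * b / ((a + b) ** 2 * (a + b + 1.0))
            return mean / var
        c0 = chi(a0 + n0, b0 + n1)
        c1 = chi(a0 + n1, b0 + n0)
        return c0 / (c0 + c1)

    def choice_nll(state, action, goal):
        q1 = {}
        for a in ACTS:
            if state == "S1":
                total = 0.0
                for s2 in graph_succ[("S1", a)]:
                    best = max(
                        sum(
                            T[(s2, a2)][o]
                            * oracle_goal_reward(o, goal, outcome_colors, coin_values)
                            for o in graph_succ[(s2, a2)]
                        )
                        for a2 in ACTS
                    )
                    total += T[("S1", a)][s2] * best
                q_mb = total
            else:
                q_mb = sum(
                    T[(state, a)][o]
                    * oracle_goal_reward(o, goal, outcome_colors, coin_values)
                    for o in graph_succ[(state, a)]
                )
            q1[a] = p_mb * q_mb + (1.0 - p_mb) * qmf[(state, a)]
        tau = tau_of(p_mb)
        zs = {a: tau * q1[a] for a in ACTS}
        m = max(zs.values())
        denom = sum(math.exp(z - m) for z in zs.values())
        pc = math.exp(zs[action] - m) / denom
        return -math.log(max(pc, prob_floor))

    def learn_transition(s, a, observed):
        spes.append(1.0 - T[(s, a)][observed])
        for sp in graph_succ[(s, a)]:
            target = 1.0 if sp == observed else 0.0
            T[(s, a)][sp] += params["alpha_mb"] * (target - T[(s, a)][sp])

    for row in log_rows:
        if row["is_pretraining"]:
            learn_transition("S1", row["a1"], row["s2"])
            learn_transition(row["s2"], row["a2"], row["s_outcome"])
            continue
        goal = row["goal"]
        nll += choice_nll("S1", row["a1"], goal)
        learn_transition("S1", row["a1"], row["s2"])
        nll += choice_nll(row["s2"], row["a2"], goal)
        learn_transition(row["s2"], row["a2"], row["s_outcome"])

        rpe1 = qmf[(row["s2"], row["a2"])] - qmf[("S1", row["a1"])]
        qmf[("S1", row["a1"])] += params["alpha_mf"] * rpe1
        omega = min(max(omega + params["eta"] * (abs(rpe1) - omega), 0.0), rpe_max)
        rpe2 = row["reward"] - qmf[(row["s2"], row["a2"])]
        qmf[(row["s2"], row["a2"])] += params["alpha_mf"] * rpe2
        omega = min(max(omega + params["eta"] * (abs(rpe2) - omega), 0.0), rpe_max)

        chi_mb = chi_mb_now()
        chi_mf = (rpe_max - omega) / rpe_max
        beta = params["A_beta"] / (1.0 + math.exp(big_b * chi_mf))
        gamma = params["A_gamma"] / (1.0 + math.exp(big_b * chi_mb))
        p_mb = min(max(p_mb + beta * (1.0 - p_mb) - gamma * p_mb, 0.0), 1.0)
    return nll


def log_to_rows(log):
    """DataFrame -> list of plain dicts for the oracle replay."""
    return log.to_dict(orient="records")


def graph_dicts(graph):
    """Extract plain-dict structure from a TaskGraph for the oracles."""
    succ = {k: tuple(v) for k, v in graph.successor_map.items()}
    return succ, dict(graph.outcome_colors), dict(graph.coin_values)
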