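"""Compiled trial-replay kernel used by likelihood evaluation.

Maximum-likelihood fitting evaluates the session likelihood thousands of
times per subject, so the replay loop is implemented once more here as a
numba kernel over integer-coded trial arrays.  Semantics are defined by
the pure-Python agent in :mod:`arbrl.arbitration`; agreement between the
two routes is enforced by the test suite.

Latent column layout (one row per trial; NaN where not applicable):
0 spe1, 1 spe2, 2 rpe1, 3 rpe2, 4 chi_mb, 5 chi_mf, 6 p_mb, 7 tau1,
8 tau2, 9 P(chosen a1), 10 P(chosen a2), 11 P(right | stage 1),
12 P(right | stage 2).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_LATENTS = 13

# exploitation variant codes
TAU_FIXED = 0
TAU_LOGISTIC = 1
TAU_LINEAR = 2
TAU_WEIGHTED = 3


@njit(cache=True)
def _tau(code, p_mb, t1, t2, t3, t4):
    if code == TAU_FIXED:
        return t1
    if code == TAU_LOGISTIC:
        return t1 + (t2 - t1) / (1.0 + math.exp(-t3 * (p_mb - t4)))
    if code == TAU_LINEAR:
        return p_mb * t1
    return p_mb * t1 + (1.0 - p_mb) * t2


@njit(cache=True)
def _p_first(q0, q1, tau):
    # stable two-action softmax: probability of action 0
    z0 = tau * q0
    z1 = tau * q1
    m = z0 if z0 > z1 else z1
    e0 = math.exp(z0 - m)
    e1 = math.exp(z1 - m)
    return e0 / (e0 + e1)


@njit(cache=True)
def _chi_mb(pa, pb, n0, n1):
    a0 = pa + n0
    b0 = pb + n1
    chi0 = (a0 + b0) * (a0 + b0 + 1.0) / b0
    a1 = pa + n1
    b1 = pb + n0
    chi1 = (a1 + b1) * (a1 + b1 + 1.0) / b1
    return chi0 / (chi0 + chi1)


@njit(cache=True)
def replay(
    is_pre,      # (n,) uint8
    goal,        # (n,) int64, row index into rtab
    a1,          # (n,) int64 in {0,1}
    s2,          # (n,) int64 second-stage state index
    a2,          # (n,) int64
    out,         # (n,) int64 outcome index
    reward,      # (n,) float64
    s1_succ,     # (2,2) int64: action, slot -> second-stage index
    s2_succ,     # (n2,2,2) int64: state, action, slot -> outcome index
    rtab,        # (n_goals, n_out) float64 goal-conditional rewards
    eps,         # zero-SPE threshold
    window,      # SPE window length
    pa, pb,      # Beta prior counts
    rpe_max,
    big_b,       # rate-function steepness B
    alpha_mb, alpha_mf, eta, a_beta, a_gamma,
    tau_code, t1, t2, t3, t4,
    include_pre_ll,
    p_mb0,
    prob_floor,
    latents,     # (n, N_LATENTS) float64, written in place
):
    n = is_pre.shape[0]
    n2 = s2_succ.shape[0]

    T1 = np.full((2, 2), 0.5)
    T2 = np.full((n2, 2, 2), 0.5)
    q_mf1 = np.zeros(2)
    q_mf2 = np.zeros((n2, 2))

    flags = np.zeros(window, dtype=np.int64)  # circular zero-SPE buffer
    n_hist = 0
    head = 0
    n0 = 0

    omega = 0.0
    p_mb = p_mb0
    nll = 0.0
    q2max = np.zeros(n2)
    latents[:] = np.nan

    for t in range(n):
        g = goal[t]
        pre = is_pre[t] == 1
        model_decisions = (not pre) or include_pre_ll

        tau_t = _tau(tau_code, p_mb, t1, t2, t3, t4)

        # ---- decision 1
        if model_decisions:
            for s in range(n2):
                best = -1.0e300
                for a in range(2):
                    v = (
                        T2[s, a, 0] * rtab[g, s2_succ[s, a, 0]]
                        + T2[s, a, 1] * rtab[g, s2_succ[s, a, 1]]
                    )
                    if v > best:
                        best = v
                q2max[s] = best
            qa0 = T1[0, 0] * q2max[s1_succ[0, 0]] + T1[0, 1] * q2max[s1_succ[0, 1]]
            qa1 = T1[1, 0] * q2max[s1_succ[1, 0]] + T1[1, 1] * q2max[s1_succ[1, 1]]
            qarb0 = p_mb * qa0 + (1.0 - p_mb) * q_mf1[0]
            qarb1 = p_mb * qa1 + (1.0 - p_mb) * q_mf1[1]
            pL = _p_first(qarb0, qarb1, tau_t)
            pc = pL if a1[t] == 0 else 1.0 - pL
            if pc < prob_floor:
                pc = prob_floor
            nll -= math.log(pc)
            latents[t, 7] = tau_t
            latents[t, 9] = pc
            latents[t, 11] = 1.0 - pL

        # ---- first transition: SPE, T update, window push
        slot = 0 if s1_succ[a1[t], 0] == s2[t] else 1
        spe1 = 1.0 - T1[a1[t], slot]
        for k in range(2):
            target = 1.0 if k == slot else 0.0
            T1[a1[t], k] += alpha_mb * (target - T1[a1[t], k])
        flag = 1 if spe1 <= eps else 0
        if n_hist == window:
            n0 -= flags[head]
        else:
            n_hist += 1
        flags[head] = flag
        n0 += flag
        head = (head + 1) % window
        latents[t, 0] = spe1

        # ---- decision 2 (planning sees the updated T)
        s = s2[t]
        if model_decisions:
            q20 = (
                T2[s, 0, 0] * rtab[g, s2_succ[s, 0, 0]]
                + T2[s, 0, 1] * rtab[g, s2_succ[s, 0, 1]]
            )
            q21 = (
                T2[s, 1, 0] * rtab[g, s2_succ[s, 1, 0]]
                + T2[s, 1, 1] * rtab[g, s2_succ[s, 1, 1]]
            )
            qarb0 = p_mb * q20 + (1.0 - p_mb) * q_mf2[s, 0]
            qarb1 = p_mb * q21 + (1.0 - p_mb) * q_mf2[s, 1]
            pL = _p_first(qarb0, qarb1, tau_t)
            pc = pL if a2[t] == 0 else 1.0 - pL
            if pc < prob_floor:
                pc = prob_floor
            nll -= math.log(pc)
            latents[t, 8] = tau_t
            latents[t, 10] = pc
            latents[t, 12] = 1.0 - pL

        # ---- second transition
        slot = 0 if s2_succ[s, a2[t], 0] == out[t] else 1
        spe2 = 1.0 - T2[s, a2[t], slot]
        for k in range(2):
            target = 1.0 if k == slot else 0.0
            T2[s, a2[t], k] += alpha_mb * (target - T2[s, a2[t], k])
        flag = 1 if spe2 <= eps else 0
        if n_hist == window:
            n0 -= flags[head]
        else:
            n_hist += 1
        flags[head] = flag
        n0 += flag
        head = (head + 1) % window
        latents[t, 1] = spe2

        if pre:
            # reward-free familiarization: no value learning, no arbitration
            continue

        # ---- SARSA (bootstrap step, then terminal step) + Pearce-Hall
        rpe1 = q_mf2[s, a2[t]] - q_mf1[a1[t]]
        q_mf1[a1[t]] += alpha_mf * rpe1
        omega += eta * (abs(rpe1) - omega)
        if omega < 0.0:
            omega = 0.0
        elif omega > rpe_max:
            omega = rpe_max
        rpe2 = reward[t] - q_mf2[s, a2[t]]
        q_mf2[s, a2[t]] += alpha_mf * rpe2
        omega += eta * (abs(rpe2) - omega)
        if omega < 0.0:
            omega = 0.0
        elif omega > rpe_max:
            omega = rpe_max
        latents[t, 2] = rpe1
        latents[t, 3] = rpe2

        # ---- arbitration: reliabilities, rates, Euler step on P_MB
        chi_mb = _chi_mb(pa, pb, float(n0), float(n_hist - n0))
        chi_mf = (rpe_max - omega) / rpe_max
        beta = a_beta / (1.0 + math.exp(big_b * chi_mf))
        gamma = a_gamma / (1.0 + math.exp(big_b * chi_mb))
        p_mb = p_mb + beta * (1.0 - p_mb) - gamma * p_mb
        if p_mb < 0.0:
            p_mb = 0.0
        elif p_mb > 1.0:
            p_mb = 1.0
        latents[t, 4] = chi_mb
        latents[t, 5] = chi_mf
        latents[t, 6] = p_mb

    return nll


@njit(cache=True)
def simulate(
    is_pre,      # (n,) uint8
    goal,        # (n,) int64
    p_first,     # (n,) float64 true prob of the first-listed successor
    s1_succ, s2_succ, rtab,
    eps, window, pa, pb, rpe_max, big_b,
    alpha_mb, alpha_mf, eta, a_beta, a_gamma,
    tau_code, t1, t2, t3, t4,
    pre_full,    # model pre-training decisions/rewards like main trials
    p_mb0,
    u,           # (n, 4) float64 uniforms: a1, transition 1, a2, transition 2
    a1, s2, a2, out, reward,  # (n,) int64/float64 outputs, written in place
    latents,     # (n, N_LATENTS) float64, written in place
):
    """Generative counterpart of :func:`replay`; same latent layout.

    Actions are drawn from the agent's softmax (uniformly during reward-
    free pre-training), transitions from the task's true probabilities via
    the supplied uniform variates.
    """
    n = is_pre.shape[0]
    n2 = s2_succ.shape[0]

    T1 = np.full((2, 2), 0.5)
    T2 = np.full((n2, 2, 2), 0.5)
    q_mf1 = np.zeros(2)
    q_mf2 = np.zeros((n2, 2))

    flags = np.zeros(window, dtype=np.int64)
    n_hist = 0
    head = 0
    n0 = 0

    omega = 0.0
    p_mb = p_mb0
    q2max = np.zeros(n2)
    latents[:] = np.nan

    for t in range(n):
        g = goal[t]
        pre = is_pre[t] == 1
        modeled = (not pre) or pre_full
        tau_t = _tau(tau_code, p_mb, t1, t2, t3, t4)

        # ---- decision 1
        if modeled:
            for s in range(n2):
                best = -1.0e300
                for a in range(2):
                    v = (
                        T2[s, a, 0] * rtab[g, s2_succ[s, a, 0]]
                        + T2[s, a, 1] * rtab[g, s2_succ[s, a, 1]]
                    )
                    if v > best:
                        best = v
                q2max[s] = best
            qa0 = T1[0, 0] * q2max[s1_succ[0, 0]] + T1[0, 1] * q2max[s1_succ[0, 1]]
            qa1 = T1[1, 0] * q2max[s1_succ[1, 0]] + T1[1, 1] * q2max[s1_succ[1, 1]]
            qarb0 = p_mb * qa0 + (1.0 - p_mb) * q_mf1[0]
            qarb1 = p_mb * qa1 + (1.0 - p_mb) * q_mf1[1]
            pL = _p_first(qarb0, qarb1, tau_t)
        else:
            pL = 0.5
        a1[t] = 0 if u[t, 0] < pL else 1
        if modeled:
            latents[t, 7] = tau_t
            latents[t, 9] = pL if a1[t] == 0 else 1.0 - pL
            latents[t, 11] = 1.0 - pL

        slot = 0 if u[t, 1] < p_first[t] else 1
        s2[t] = s1_succ[a1[t], slot]
        spe1 = 1.0 - T1[a1[t], slot]
        for k in range(2):
            target = 1.0 if k == slot else 0.0
            T1[a1[t], k] += alpha_mb * (target - T1[a1[t], k])
        flag = 1 if spe1 <= eps else 0
        if n_hist == window:
            n0 -= flags[head]
        else:
            n_hist += 1
        flags[head] = flag
        n0 += flag
        head = (head + 1) % window
        latents[t, 0] = spe1

        # ---- decision 2
        s = s2[t]
        if modeled:
            q20 = (
                T2[s, 0, 0] * rtab[g, s2_succ[s, 0, 0]]
                + T2[s, 0, 1] * rtab[g, s2_succ[s, 0, 1]]
            )
            q21 = (
                T2[s, 1, 0] * rtab[g, s2_succ[s, 1, 0]]
                + T2[s, 1, 1] * rtab[g, s2_succ[s, 1, 1]]
            )
            qarb0 = p_mb * q20 + (1.0 - p_mb) * q_mf2[s, 0]
            qarb1 = p_mb * q21 + (1.0 - p_mb) * q_mf2[s, 1]
            pL = _p_first(qarb0, qarb1, tau_t)
        else:
            pL = 0.5
        a2[t] = 0 if u[t, 2] < pL else 1
        if modeled:
            latents[t, 8] = tau_t
            latents[t, 10] = pL if a2[t] == 0 else 1.0 - pL
            latents[t, 12] = 1.0 - pL

        slot = 0 if u[t, 3] < p_first[t] else 1
        out[t] = s2_succ[s, a2[t], slot]
        spe2 = 1.0 - T2[s, a2[t], slot]
        for k in range(2):
            target = 1.0 if k == slot else 0.0
            T2[s, a2[t], k] += alpha_mb * (target - T2[s, a2[t], k])
        flag = 1 if spe2 <= eps else 0
        if n_hist == window:
            n0 -= flags[head]
        else:
            n_hist += 1
        flags[head] = flag
        n0 += flag
        head = (head + 1) % window
        latents[t, 1] = spe2

        if pre and not pre_full:
            reward[t] = 0.0
            continue

        reward[t] = rtab[g, out[t]]

        rpe1 = q_mf2[s, a2[t]] - q_mf1[a1[t]]
        q_mf1[a1[t]] += alpha_mf * rpe1
        omega += eta * (abs(rpe1) - omega)
        if omega < 0.0:
            omega = 0.0
        elif omega > rpe_max:
            omega = rpe_max
        rpe2 = reward[t] - q_mf2[s, a2[t]]
        q_mf2[s, a2[t]] += alpha_mf * rpe2
        omega += eta * (abs(rpe2) - omega)
        if omega < 0.0:
            omega = 0.0
        elif omega > rpe_max:
            omega = rpe_max
        latents[t, 2] = rpe1
        latents[t, 3] = rpe2

        chi_mb = _chi_mb(pa, pb, float(n0), float(n_hist - n0))
        chi_mf = (rpe_max - omega) / rpe_max
        beta = a_beta / (1.0 + math.exp(big_b * chi_mf))
        gamma = a_gamma / (1.0 + math.exp(big_b * chi_mb))
        p_mb = p_mb + beta * (1.0 - p_mb) - gamma * p_mb
        if p_mb < 0.0:
            p_mb = 0.0
        elif p_mb > 1.0:
            p_mb = 1.0
        latents[t, 4] = chi_mb
        latents[t, 5] = chi_mf
        latents[t, 6] = p_mb
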