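"""Arbitration between the model-based and model-free controllers.

Each system carries a reliability index chi in (0, 1): the model-based
system's reliability is the normalized inverse dispersion of a conjugate
(Beta) posterior over the probability of "zero" state prediction errors in
a recent window; the model-free system's is the complement of a
Pearce-Hall associability Omega that tracks the unsigned reward prediction
error.  The two reliabilities drive a two-state transition process on the
model choice probability P_MB:

    dP_MB/dt = beta * (1 - P_MB) - gamma * P_MB

with beta (MF -> MB) a decreasing function of chi_MF and gamma (MB -> MF)
a decreasing function of chi_MB.  P_MB weights both the value integration
Q_arb = P_MB * Q_MB + (1 - P_MB) * Q_MF and, in the dynamic-exploitation
variants, the softmax inverse temperature tau.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .learners import (
    MFValues,
    TransitionModel,
    plan_mb_values,
    sarsa_update,
    state_prediction_error,
    update_transition_model,
)
from .task import ACTIONS, TaskGraph, goal_reward


# ---------------------------------------------------------------------------
# reliability estimators
# ---------------------------------------------------------------------------

@dataclass
class MBReliabilityState:
    """Empirical-Bayes reliability of the model-based system.

    Events in the SPE history ``D`` are classified as "zero" when the SPE
    is at most ``zero_threshold``.  theta_0 (probability of a zero-SPE
    event) and theta_1 (non-zero) get conjugate Beta posteriors from the
    window counts on top of the (a0, b0) prior; each system's precision
    chi_i is the posterior mean over posterior variance (inverse index of
    dispersion), and the reliability is chi_0 / (chi_0 + chi_1).
    """

    zero_threshold: float = 0.2
    window: int = 20
    prior_counts: tuple[float, float] = (1.0, 1.0)
    history: deque = field(default_factory=lambda: deque(maxlen=20))

    def __post_init__(self) -> None:
        if self.zero_threshold < 0:
            raise ValueError("zero_threshold must be >= 0")
        if min(self.prior_counts) <= 0:
            raise ValueError("prior counts must be positive")
        self.history = deque(self.history, maxlen=self.window)

    def observe(self, spe: float) -> None:
        self.history.append(float(spe))


def _beta_precision(a: float, b: float) -> float:
    # mean/variance of Beta(a, b) collapses to (a+b)(a+b+1)/b
    return (a + b) * (a + b + 1.0) / b


def mb_reliability(state: MBReliabilityState) -> float:
    """chi_MB in (0, 1) from the current SPE window."""
    a0, b0 = state.prior_counts
    n0 = sum(1 for spe in state.history if spe <= state.zero_threshold)
    n1 = len(state.history) - n0
    chi0 = _beta_precision(a0 + n0, b0 + n1)
    chi1 = _beta_precision(a0 + n1, b0 + n0)
    return chi0 / (chi0 + chi1)


@dataclass
class MFReliabilityState:
    """Pearce-Hall reliability of the model-free system.

    Omega tracks the unsigned RPE with rate eta; chi_MF is the complement
    normalized by the ceiling rpe_max, so perfect reward prediction gives
    chi_MF = 1 and errors at the ceiling give 0.
    """

    eta: float = 0.2
    rpe_max: float = 40.0
    omega: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta={self.eta} outside [0,1]")
        if self.rpe_max <= 0:
            raise ValueError("rpe_max must be positive")

    @property
    def chi(self) -> float:
        return (self.rpe_max - self.omega) / self.rpe_max


def mf_reliability_update(
    state: MFReliabilityState, abs_rpe: float
) -> MFReliabilityState:
    """Omega <- Omega + eta * (|RPE| - Omega), clipped into [0, rpe_max]."""
    if abs_rpe < 0:
        raise ValueError("abs_rpe must be >= 0")
    omega = state.omega + state.eta * (abs_rpe - state.omega)
    omega = min(max(omega, 0.0), state.rpe_max)
    return replace(state, omega=omega)


# ---------------------------------------------------------------------------
# P_MB dynamics and value integration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArbitrationParams:
    """Amplitudes of the two transition rates and the shared steepness B."""

    a_beta: float = 1.0
    a_gamma: float = 1.0
    steepness: float = 6.0   # fixed constant B, not a fitted parameter

    def __post_init__(self) -> None:
        if self.a_beta < 0 or self.a_gamma < 0:
            raise ValueError("rate amplitudes must be >= 0")


def transition_rates(
    chi_mf: float, chi_mb: float, params: ArbitrationParams
) -> tuple[float, float]:
    """(beta, gamma): each A / (1 + exp(B * chi)), decreasing in its chi.

    A reliable system should retain control, so the rate of leaving it
    falls as its reliability rises.
    """
    b = params.steepness
    beta = params.a_beta / (1.0 + math.exp(b * chi_mf))
    gamma = params.a_gamma / (1.0 + math.exp(b * chi_mb))
    return beta, gamma


def update_model_choice_prob(p_mb: float, beta: float, gamma: float) -> float:
    """One Euler step (dt = 1) of dP/dt = beta(1-P) - gamma P, clipped."""
    p = p_mb + beta * (1.0 - p_mb) - gamma * p_mb
    return min(max(p, 0.0), 1.0)


def integrate_values(
    q_mb: Mapping, q_mf: Mapping, p_mb: float
) -> dict:
    """Q_arb = P_MB * Q_MB + (1 - P_MB) * Q_MF, elementwise."""
    if set(q_mb) != set(q_mf):
        raise ValueError("mismatched (state, action) sets")
    return {k: p_mb * q_mb[k] + (1.0 - p_mb) * q_mf[k] for k in q_mb}


# ---------------------------------------------------------------------------
# exploitation (softmax inverse temperature)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExploitationSpec:
    """How the softmax inverse temperature tau depends on P_MB.

    variants: ``fixed`` (constant tau), ``logistic`` (c1..c4 sigmoid in
    P_MB), ``linear`` (tau = P_MB * c), ``weighted``
    (tau = P_MB * tau_mb + (1 - P_MB) * tau_mf).
    """

    variant: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        required = {
            "fixed": ("tau",),
            "logistic": ("c1", "c2", "c3", "c4"),
            "linear": ("c",),
            "weighted": ("tau_mb", "tau_mf"),
        }
        if self.variant not in required:
            raise ValueError(f"unknown exploitation variant {self.variant!r}")
        missing = [k for k in required[self.variant] if k not in self.params]
        if missing:
            raise ValueError(f"{self.variant}: missing parameters {missing}")
        if any(v < 0 for v in self.params.values()):
            raise ValueError("exploitation parameters must be >= 0")
        if self.variant == "logistic" and self.params["c2"] < self.params["c1"]:
            raise ValueError("logistic variant requires c2 >= c1")


def dynamic_exploitation(p_mb: float, spec: ExploitationSpec) -> float:
    """tau as a function of the model choice probability."""
    p = spec.params
    if spec.variant == "fixed":
        return p["tau"]
    if spec.variant == "logistic":
        return p["c1"] + (p["c2"] - p["c1"]) / (
            1.0 + math.exp(-p["c3"] * (p_mb - p["c4"]))
        )
    if spec.variant == "linear":
        return p_mb * p["c"]
    return p_mb * p["tau_mb"] + (1.0 - p_mb) * p["tau_mf"]


def softmax_policy(q: Sequence[float], tau: float) -> np.ndarray:
    """P(a) proportional to exp(tau * Q(a)), max-subtracted for stability."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    z = tau * np.asarray(q, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite action values")
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# the composed agent
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentParams:
    """Free parameters of one arbitration agent."""

    alpha_mb: float         # transition-model learning rate (kappa)
    alpha_mf: float         # SARSA learning rate
    eta: float              # Pearce-Hall associability rate
    a_beta: float           # MF -> MB rate amplitude
    a_gamma: float          # MB -> MF rate amplitude
    exploitation: ExploitationSpec


@dataclass(frozen=True)
class ArbConfig:
    """Structural constants of the arbitration machinery."""

    spe_zero_threshold: float = 0.2
    spe_window: int = 20
    spe_prior: tuple[float, float] = (1.0, 1.0)
    rate_steepness: float = 6.0
    p_mb_init: float = 0.5
    rpe_max: float | None = None   # None -> max coin value of the graph
    prob_floor: float = 1e-12      # likelihood floor before log


@dataclass
class AgentState:
    """All latent variables of one arbitration agent."""

    T: TransitionModel
    q_mf: MFValues
    mb_rel: MBReliabilityState
    mf_rel: MFReliabilityState
    p_mb: float

    @property
    def chi_mb(self) -> float:
        return mb_reliability(self.mb_rel)

    @property
    def chi_mf(self) -> float:
        return self.mf_rel.chi


def init_agent_state(
    params: AgentParams, graph: TaskGraph, config: ArbConfig = ArbConfig()
) -> AgentState:
    rpe_max = config.rpe_max if config.rpe_max is not None else graph.max_coin_value
    return AgentState(
        T=TransitionModel.uniform(graph, kappa=params.alpha_mb),
        q_mf=MFValues.zeros(alpha=params.alpha_mf),
        mb_rel=MBReliabilityState(
            zero_threshold=config.spe_zero_threshold,
            window=config.spe_window,
            prior_counts=config.spe_prior,
        ),
        mf_rel=MFReliabilityState(eta=params.eta, rpe_max=rpe_max),
        p_mb=config.p_mb_init,
    )


def _full_q(graph: TaskGraph, values) -> dict:
    return {
        (s, a): values.value(s, a)
        for s in graph.decision_states()
        for a in ACTIONS
    }


def _decide(
    state: AgentState,
    params: AgentParams,
    graph: TaskGraph,
    goal: str,
    s: str,
    rng: np.random.Generator | None,
    forced_action: str | None,
) -> tuple[str, np.ndarray, float]:
    """One decision: plan, integrate, pick tau, softmax, choose."""
    q_mb = plan_mb_values(state.T, graph, goal)
    q_arb = integrate_values(
        _full_q(graph, q_mb), _full_q(graph, state.q_mf), state.p_mb
    )
    tau = dynamic_exploitation(state.p_mb, params.exploitation)
    probs = softmax_policy([q_arb[(s, a)] for a in ACTIONS], tau)
    if forced_action is not None:
        action = forced_action
    else:
        action = ACTIONS[int(rng.random() >= probs[0])]
    return action, probs, tau


def agent_trial(
    state: AgentState,
    params: AgentParams,
    graph: TaskGraph,
    goal: str,
    uncertainty: str,
    sample_next: Callable[[str, str], str],
    rng: np.random.Generator | None = None,
    config: ArbConfig = ArbConfig(),
    forced: tuple[str, str, str, str] | None = None,
) -> tuple[tuple[str, str], AgentState, dict]:
    """Run one full trial, mutating a copy of the agent state.

    ``sample_next(state, action)`` supplies environment transitions; when
    ``forced`` = (a1, s2, a2, s_outcome) is given the logged experience is
    replayed instead (used for likelihoods and replay/simulate agreement
    checks).  Returns the actions taken, the updated state, and the trial's
    latent record.
    """
    if forced is None and rng is None:
        raise ValueError("need an rng unless actions are forced")
    latents: dict = {"spe": [], "rpe": [], "action_probs": [], "tau": []}
    s1 = graph.first_stage_state

    # --- decision 1
    a1, probs1, tau1 = _decide(
        state, params, graph, goal, s1, rng, forced[0] if forced else None
    )
    latents["action_probs"].append(probs1.tolist())
    latents["tau"].append(tau1)
    s2 = forced[1] if forced else sample_next(s1, a1)

    # --- observe first transition: SPE, T update, MB reliability
    spe1 = state_prediction_error(state.T, s1, a1, s2)
    state.T = update_transition_model(state.T, s1, a1, s2)
    state.mb_rel.observe(spe1)
    latents["spe"].append(spe1)

    # --- decision 2 (Q_MB replanned with the updated T)
    a2, probs2, tau2 = _decide(
        state, params, graph, goal, s2, rng, forced[2] if forced else None
    )
    latents["action_probs"].append(probs2.tolist())
    latents["tau"].append(tau2)
    s_out = forced[3] if forced else sample_next(s2, a2)

    spe2 = state_prediction_error(state.T, s2, a2, s_out)
    state.T = update_transition_model(state.T, s2, a2, s_out)
    state.mb_rel.observe(spe2)
    latents["spe"].append(spe2)

    # --- reward and the two SARSA steps (bootstrap, then terminal)
    reward = goal_reward(s_out, goal, graph)
    state.q_mf, rpe1 = sarsa_update(state.q_mf, s1, a1, 0.0, s2, a2)
    state.mf_rel = mf_reliability_update(state.mf_rel, abs(rpe1))
    state.q_mf, rpe2 = sarsa_update(state.q_mf, s2, a2, reward, None, None)
    state.mf_rel = mf_reliability_update(state.mf_rel, abs(rpe2))
    latents["rpe"] = [rpe1, rpe2]

    # --- arbitration step, once per trial
    chi_mb = mb_reliability(state.mb_rel)
    chi_mf = state.mf_rel.chi
    beta, gamma = transition_rates(
        chi_mf,
        chi_mb,
        ArbitrationParams(params.a_beta, params.a_gamma, config.rate_steepness),
    )
    state.p_mb = update_model_choice_prob(state.p_mb, beta, gamma)

    latents.update(
        chi_mb=chi_mb, chi_mf=chi_mf, p_mb=state.p_mb, reward=reward
    )
    return (a1, a2), state, latents


def pretraining_trial(
    state: AgentState,
    graph: TaskGraph,
    uncertainty: str,
    sample_next: Callable[[str, str], str],
    rng: np.random.Generator,
) -> tuple[tuple[str, str], AgentState, tuple[str, str]]:
    """One reward-free familiarization trial.

    Choices are uniformly random and no reward is delivered; only the
    transition model and the SPE history are updated, emulating state-space
    learning before the incentivized sessions.
    """
    s1 = graph.first_stage_state
    a1 = ACTIONS[int(rng.integers(2))]
    s2 = sample_next(s1, a1)
    state.mb_rel.observe(state_prediction_error(state.T, s1, a1, s2))
    state.T = update_transition_model(state.T, s1, a1, s2)
    a2 = ACTIONS[int(rng.integers(2))]
    s_out = sample_next(s2, a2)
    state.mb_rel.observe(state_prediction_error(state.T, s2, a2, s_out))
    state.T = update_transition_model(state.T, s2, a2, s_out)
    return (a1, a2), state, (s2, s_out)
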