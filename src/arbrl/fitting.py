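"""Maximum-likelihood fitting of the arbitration model variants.

Five nested variants are fitted per subject by multi-start Nelder-Mead
minimization of the negative log-likelihood of the logged choices:

====================  =========================================================
Arb                   shared learning rate alpha, fixed tau
Arb_a                 separate alpha_mb / alpha_mf, fixed tau
Arb_a_t1              + logistic tau(P_MB) with parameters c1..c4
Arb_a_t2              + linear tau = P_MB * c
Arb_a_t3              + weighted tau = P_MB * tau_mb + (1 - P_MB) * tau_mf
====================  =========================================================

All parameters are lower-bounded at zero; the simplex search runs in an
unconstrained space mapped onto the open boxes by sigmoids.  Models are
compared with BIC and a group Bayes factor computed from summed BIC
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _engine
from .arbitration import AgentParams, ArbConfig, ExploitationSpec
from .task import FLEXIBLE, TaskGraph, build_task_graph, goal_color

_TAU_CAP = 50.0
_AMP_CAP = 10.0

_VARIANT_CODES = {
    "fixed": _engine.TAU_FIXED,
    "logistic": _engine.TAU_LOGISTIC,
    "linear": _engine.TAU_LINEAR,
    "weighted": _engine.TAU_WEIGHTED,
}


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: its free parameters, bounds, and tau rule."""

    name: str
    variant: str                      # exploitation variant wired in
    fit_params: tuple[tuple[str, float], ...]  # (name, cap); cap 1.0 = rate

    def start_ranges(self) -> np.ndarray:
        """Per-parameter restart ranges in the unconstrained space.

        tau-like parameters (cap 50) start low: softmax saturates once
        tau times the value scale passes a few nats, leaving the simplex
        on a flat plateau, so their starts cover roughly 0.02-10 rather
        than the upper half of the box.
        """
        lo, hi = [], []
        for _, cap in self.fit_params:
            if cap >= _TAU_CAP:
                lo.append(-8.0)
                hi.append(-1.0)
            else:
                lo.append(-2.5)
                hi.append(2.5)
        return np.array([lo, hi])

    @property
    def param_names(self) -> tuple[str, ...]:
        names = []
        for p, _ in self.fit_params:
            names.append("c2" if p == "c2_gap" else p)
        return tuple(names)

    @property
    def k(self) -> int:
        return len(self.fit_params)

    def to_params(self, z: np.ndarray) -> dict[str, float]:
        """Unconstrained vector -> named parameters inside their bounds."""
        out: dict[str, float] = {}
        for (name, cap), zi in zip(self.fit_params, z):
            # overflow-safe sigmoid; the simplex may wander to large |z|
            out[name] = cap * 0.5 * (1.0 + math.tanh(zi / 2.0))
        if "c2_gap" in out:  # logistic upper bound rides on c1: c2 >= c1
            out["c2"] = out["c1"] + out.pop("c2_gap")
        return out

    def to_vector(self, params: Mapping[str, float]) -> np.ndarray:
        """Inverse of :meth:`to_params` (for injecting known start points)."""
        z = np.empty(self.k)
        for i, (name, cap) in enumerate(self.fit_params):
            if name == "c2_gap":
                v = params["c2"] - params["c1"]
            else:
                v = params[name]
            frac = min(max(v / cap, 1e-9), 1.0 - 1e-9)
            z[i] = math.log(frac / (1.0 - frac))
        return z

    def exploitation(self, params: Mapping[str, float]) -> ExploitationSpec:
        keys = {
            "fixed": ("tau",),
            "logistic": ("c1", "c2", "c3", "c4"),
            "linear": ("c",),
            "weighted": ("tau_mb", "tau_mf"),
        }[self.variant]
        return ExploitationSpec(self.variant, {k: params[k] for k in keys})

    def agent_params(self, params: Mapping[str, float]) -> AgentParams:
        alpha_mb = params.get("alpha_mb", params.get("alpha"))
        alpha_mf = params.get("alpha_mf", params.get("alpha"))
        return AgentParams(
            alpha_mb=alpha_mb,
            alpha_mf=alpha_mf,
            eta=params["eta"],
            a_beta=params["A_beta"],
            a_gamma=params["A_gamma"],
            exploitation=self.exploitation(params),
        )

    def engine_args(
        self, params: Mapping[str, float]
    ) -> tuple[float, float, float, float, float, int, float, float, float, float]:
        ap = self.agent_params(params)
        t = [0.0, 0.0, 0.0, 0.0]
        order = {
            "fixed": ("tau",),
            "logistic": ("c1", "c2", "c3", "c4"),
            "linear": ("c",),
            "weighted": ("tau_mb", "tau_mf"),
        }[self.variant]
        for i, key in enumerate(order):
            t[i] = float(params[key])
        return (
            ap.alpha_mb, ap.alpha_mf, ap.eta, ap.a_beta, ap.a_gamma,
            _VARIANT_CODES[self.variant], t[0], t[1], t[2], t[3],
        )


def embed_params(
    target: str, source: str, params: Mapping[str, float]
) -> dict[str, float] | None:
    """Lift a simpler model's solution into a nested richer model.

    Returns parameters of ``target`` whose likelihood equals the source
    solution's exactly (the embeddings set the extra flexibility to the
    shared value), or None when no exact embedding exists.
    """
    p = dict(params)
    if target == "Arb_a" and source == "Arb":
        return {
            "alpha_mb": p["alpha"], "alpha_mf": p["alpha"], "eta": p["eta"],
            "A_beta": p["A_beta"], "A_gamma": p["A_gamma"], "tau": p["tau"],
        }
    if source == "Arb":
        base = embed_params("Arb_a", "Arb", p)
        return embed_params(target, "Arb_a", base) if base else None
    if target == "Arb_a_t3" and source == "Arb_a":
        out = {k: v for k, v in p.items() if k != "tau"}
        out.update(tau_mb=p["tau"], tau_mf=p["tau"])
        return out
    if target == "Arb_a_t1" and source == "Arb_a":
        out = {k: v for k, v in p.items() if k != "tau"}
        # flat logistic at the shared tau; c3/c4 are inert when c1 == c2
        out.update(c1=p["tau"], c2=p["tau"], c3=5.0, c4=0.5)
        return out
    if target == "Arb_a_t2" and source == "Arb_a":
        # heuristic start, not an exact embedding: tau = P_MB * c matches
        # the fixed tau at mid-range P_MB
        out = {k: v for k, v in p.items() if k != "tau"}
        out.update(c=min(2.0 * p["tau"], _TAU_CAP))
        return out
    if target == "Arb_a_t3" and source == "Arb_a_t2":
        # linear tau is the weighted blend with a zero MF component
        out = {k: v for k, v in p.items() if k != "c"}
        out.update(tau_mb=p["c"], tau_mf=1e-6)
        return out
    return None


_RATE = 1.0
MODEL_SPECS: dict[str, ModelSpec] = {
    "Arb": ModelSpec(
        "Arb", "fixed",
        (("alpha", _RATE), ("eta", _RATE), ("A_beta", _AMP_CAP),
         ("A_gamma", _AMP_CAP), ("tau", _TAU_CAP)),
    ),
    "Arb_a": ModelSpec(
        "Arb_a", "fixed",
        (("alpha_mb", _RATE), ("alpha_mf", _RATE), ("eta", _RATE),
         ("A_beta", _AMP_CAP), ("A_gamma", _AMP_CAP), ("tau", _TAU_CAP)),
    ),
    "Arb_a_t1": ModelSpec(
        "Arb_a_t1", "logistic",
        (("alpha_mb", _RATE), ("alpha_mf", _RATE), ("eta", _RATE),
         ("A_beta", _AMP_CAP), ("A_gamma", _AMP_CAP),
         ("c1", _TAU_CAP), ("c2_gap", _TAU_CAP), ("c3", _TAU_CAP),
         ("c4", _RATE)),
    ),
    "Arb_a_t2": ModelSpec(
        "Arb_a_t2", "linear",
        (("alpha_mb", _RATE), ("alpha_mf", _RATE), ("eta", _RATE),
         ("A_beta", _AMP_CAP), ("A_gamma", _AMP_CAP), ("c", _TAU_CAP)),
    ),
    "Arb_a_t3": ModelSpec(
        "Arb_a_t3", "weighted",
        (("alpha_mb", _RATE), ("alpha_mf", _RATE), ("eta", _RATE),
         ("A_beta", _AMP_CAP), ("A_gamma", _AMP_CAP),
         ("tau_mb", _TAU_CAP), ("tau_mf", _TAU_CAP)),
    ),
}


# ---------------------------------------------------------------------------
# log encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodedLog:
    """Integer-coded trial log plus graph tables for the replay kernel."""

    is_pre: np.ndarray
    goal: np.ndarray
    a1: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    out: np.ndarray
    reward: np.ndarray
    s1_succ: np.ndarray
    s2_succ: np.ndarray
    rtab: np.ndarray
    graph: TaskGraph

    @property
    def n_trials(self) -> int:
        return len(self.a1)

    @property
    def n_main_decisions(self) -> int:
        return int(2 * (self.is_pre == 0).sum())


def encode_graph(graph: TaskGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Graph tables (s1_succ, s2_succ, rtab) and the goal-label index map."""
    second_idx = {s: i for i, s in enumerate(graph.second_stage_states)}
    out_idx = {s: i for i, s in enumerate(graph.outcome_states)}

    s1_succ = np.empty((2, 2), dtype=np.int64)
    for ai, a in enumerate(("L", "R")):
        for slot, sp in enumerate(graph.successors(graph.first_stage_state, a)):
            s1_succ[ai, slot] = second_idx[sp]
    s2_succ = np.empty((len(second_idx), 2, 2), dtype=np.int64)
    for s, si in second_idx.items():
        for ai, a in enumerate(("L", "R")):
            for slot, sp in enumerate(graph.successors(s, a)):
                s2_succ[si, ai, slot] = out_idx[sp]

    goals = [FLEXIBLE] + [f"specific:{c}" for c in graph.colors]
    goal_idx = {g: i for i, g in enumerate(goals)}
    rtab = np.zeros((len(goals), len(out_idx)))
    for o, oi in out_idx.items():
        color = graph.outcome_colors[o]
        v = graph.coin_values[color]
        rtab[0, oi] = v
        for g, gi in goal_idx.items():
            if goal_color(g) == color:
                rtab[gi, oi] = v
    return s1_succ, s2_succ, rtab, goal_idx


def encode_log(log: pd.DataFrame, graph: TaskGraph | None = None) -> EncodedLog:
    """Turn a trial-log DataFrame into the kernel's integer arrays.

    Rows must be in replay order (session then trial, pre-training first);
    callers reading CSVs through :func:`arbrl.io.read_trial_log` get this
    ordering validated.
    """
    graph = graph or build_task_graph()
    s1_succ, s2_succ, rtab, goal_idx = encode_graph(graph)
    second_idx = {s: i for i, s in enumerate(graph.second_stage_states)}
    out_idx = {s: i for i, s in enumerate(graph.outcome_states)}
    act_idx = {"L": 0, "R": 1}
    try:
        goal = np.array([goal_idx[g] for g in log["goal"]], dtype=np.int64)
        a1 = np.array([act_idx[a] for a in log["a1"]], dtype=np.int64)
        a2 = np.array([act_idx[a] for a in log["a2"]], dtype=np.int64)
        s2 = np.array([second_idx[s] for s in log["s2"]], dtype=np.int64)
        out = np.array([out_idx[s] for s in log["s_outcome"]], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"log references unknown state/action/goal: {e}") from e
    is_pre = log["is_pretraining"].to_numpy().astype(np.uint8)
    reward = log["reward"].to_numpy(dtype=float)
    return EncodedLog(
        is_pre, goal, a1, s2, a2, out, reward, s1_succ, s2_succ, rtab, graph
    )


# ---------------------------------------------------------------------------
# likelihood, BIC, fitting
# ---------------------------------------------------------------------------

def session_nll(
    model: ModelSpec | str,
    params: Mapping[str, float],
    log: pd.DataFrame | EncodedLog,
    graph: TaskGraph | None = None,
    config: ArbConfig = ArbConfig(),
    include_pretraining: bool = False,
    return_latents: bool = False,
):
    """Negative log-likelihood of the logged choices under the model.

    The agent is replayed deterministically through the logged experience
    (actions and transitions read from the log, never sampled),
    accumulating -log P(logged action) at every main-session decision.
    Pre-training trials train the transition model and SPE history but by
    default contribute no likelihood terms.
    """
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    enc = log if isinstance(log, EncodedLog) else encode_log(log, graph)
    rpe_max = (
        config.rpe_max if config.rpe_max is not None else enc.graph.max_coin_value
    )
    latents = np.empty((enc.n_trials, _engine.N_LATENTS))
    nll = _engine.replay(
        enc.is_pre, enc.goal, enc.a1, enc.s2, enc.a2, enc.out, enc.reward,
        enc.s1_succ, enc.s2_succ, enc.rtab,
        config.spe_zero_threshold, config.spe_window,
        config.spe_prior[0], config.spe_prior[1],
        rpe_max, config.rate_steepness,
        *spec.engine_args(params),
        include_pretraining, config.p_mb_init, config.prob_floor,
        latents,
    )
    if not math.isfinite(nll):
        raise FloatingPointError("non-finite likelihood")
    if return_latents:
        cols = [
            "spe1", "spe2", "rpe1", "rpe2", "chi_mb", "chi_mf", "p_mb",
            "tau1", "tau2", "p_chosen1", "p_chosen2", "p_right1", "p_right2",
        ]
        return nll, pd.DataFrame(latents, columns=cols)
    return nll


def bic_score(nll: float, k: int, n: int) -> float:
    """BIC = 2 * NLL + k * ln(n)."""
    if n <= 0:
        raise ValueError("observation count must be positive")
    if k < 0:
        raise ValueError("parameter count must be >= 0")
    return 2.0 * nll + k * math.log(n)


@dataclass
class FitResult:
    """Per-subject fit of one model variant."""

    subject: str
    model: str
    params: dict[str, float]
    nll: float
    bic: float
    n_obs: int
    restart_nlls: list[float] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "subject": self.subject,
            "model": self.model,
            "params": self.params,
            "nll": self.nll,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "restart_nlls": list(self.restart_nlls),
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: Mapping) -> "FitResult":
        return FitResult(
            subject=d["subject"], model=d["model"], params=dict(d["params"]),
            nll=d["nll"], bic=d["bic"], n_obs=d["n_obs"],
            restart_nlls=list(d["restart_nlls"]), seed=d["seed"],
        )


def fit_subject(
    model: ModelSpec | str,
    log: pd.DataFrame | EncodedLog,
    n_restarts: int = 128,
    seed: int | np.random.Generator = 0,
    *,
    subject: str = "subject",
    graph: TaskGraph | None = None,
    config: ArbConfig = ArbConfig(),
    include_pretraining: bool = False,
    init_params: Mapping[str, float] | Sequence[Mapping[str, float]] | None = None,
    maxiter: int = 400,
    xatol: float = 1e-3,
    fatol: float = 1e-3,
) -> FitResult:
    """Multi-start Nelder-Mead maximum-likelihood fit of one subject.

    Starting points are drawn uniformly in the unconstrained (sigmoid-
    transformed) parameter space, with per-parameter ranges.  When
    ``init_params`` is given — the generating point of a recovery
    experiment, or embedded solutions of nested models — the point(s)
    replace the first restart(s), so the returned NLL can never exceed
    the NLL at any of them.  A final polish pass restarts the simplex
    from the incumbent best.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    spec = MODEL_SPECS[model] if isinstance(model, str) else model
    enc = log if isinstance(log, EncodedLog) else encode_log(log, graph)
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rpe_max = (
        config.rpe_max if config.rpe_max is not None else enc.graph.max_coin_value
    )
    latents = np.empty((enc.n_trials, _engine.N_LATENTS))

    def objective(z: np.ndarray) -> float:
        nll = _engine.replay(
            enc.is_pre, enc.goal, enc.a1, enc.s2, enc.a2, enc.out, enc.reward,
            enc.s1_succ, enc.s2_succ, enc.rtab,
            config.spe_zero_threshold, config.spe_window,
            config.spe_prior[0], config.spe_prior[1],
            rpe_max, config.rate_steepness,
            *spec.engine_args(spec.to_params(z)),
            include_pretraining, config.p_mb_init, config.prob_floor,
            latents,
        )
        return nll if math.isfinite(nll) else 1e300

    lo, hi = spec.start_ranges()
    starts = [rng.uniform(lo, hi) for _ in range(n_restarts)]
    if init_params is not None:
        inits = (
            [init_params] if isinstance(init_params, Mapping) else list(init_params)
        )
        for i, p0 in enumerate(inits[: len(starts)]):
            starts[i] = spec.to_vector(p0)

    best_z, best_nll = None, math.inf
    restart_nlls: list[float] = []
    for z0 in starts:
        res = minimize(
            objective, z0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
        )
        nll = float(res.fun)
        # the start point itself is a candidate (guards against early stops)
        nll0 = objective(z0)
        if nll0 < nll:
            nll, res.x = nll0, z0
        restart_nlls.append(nll)
        if nll < best_nll:
            best_nll, best_z = nll, res.x
    if best_z is None or not math.isfinite(best_nll):
        raise RuntimeError("all restarts produced non-finite likelihoods")

    # polish: a fresh simplex at the incumbent best often escapes the
    # collapsed simplex a long Nelder-Mead run ends with
    res = minimize(
        objective, best_z, method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
    )
    if math.isfinite(res.fun) and res.fun < best_nll:
        best_nll, best_z = float(res.fun), res.x
    restart_nlls.append(float(min(best_nll, res.fun)))

    n_obs = enc.n_main_decisions + (
        int(2 * (enc.is_pre == 1).sum()) if include_pretraining else 0
    )
    return FitResult(
        subject=subject,
        model=spec.name,
        params=spec.to_params(np.asarray(best_z)),
        nll=best_nll,
        bic=bic_score(best_nll, spec.k, n_obs),
        n_obs=n_obs,
        restart_nlls=restart_nlls,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def group_bayes_factor(
    fits_ref: Sequence[FitResult], fits_alt: Sequence[FitResult]
) -> float:
    """BF = exp((sum BIC_ref - sum BIC_alt) / 2); BF > 1 favors alt.

    Summed BIC differences across subjects can be large, so the result may
    overflow to ``inf``; use :func:`log10_group_bayes_factor` for reporting.
    """
    half = log_group_bic_diff(fits_ref, fits_alt) / 2.0
    return math.exp(half) if half <= 709.0 else math.inf


def log_group_bic_diff(
    fits_ref: Sequence[FitResult], fits_alt: Sequence[FitResult]
) -> float:
    """Sum over subjects of (BIC_ref - BIC_alt), with subject matching."""
    ref = {f.subject: f for f in fits_ref}
    alt = {f.subject: f for f in fits_alt}
    if set(ref) != set(alt):
        raise ValueError("subject sets differ between the two fit lists")
    return sum(ref[s].bic - alt[s].bic for s in ref)


def log10_group_bayes_factor(
    fits_ref: Sequence[FitResult], fits_alt: Sequence[FitResult]
) -> float:
    return log_group_bic_diff(fits_ref, fits_alt) / 2.0 / math.log(10.0)


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    best_model: str
    fits: dict[str, list[FitResult]]
    paired_nll: pd.DataFrame   # per-subject NLLs of the top two models

    def __repr__(self) -> str:  # pragma: no cover
        return f"ComparisonResult(best={self.best_model})\n{self.table}"


def compare_models(
    logs: Mapping[str, pd.DataFrame | EncodedLog],
    models: Sequence[str] = tuple(MODEL_SPECS),
    base_model: str | None = None,
    n_restarts: int = 128,
    seed: int = 0,
    **fit_kwargs,
) -> ComparisonResult:
    """Fit every (subject, model) pair and compare by group Bayes factor.

    Bayes factors are reported against ``base_model`` (``Arb`` when
    present); the winner is the model with the smallest summed BIC.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    if base_model is None:
        base_model = "Arb" if "Arb" in models else models[0]
    ss = np.random.SeedSequence(seed)
    subjects = list(logs)
    children = ss.spawn(len(subjects) * len(models))
    fits: dict[str, list[FitResult]] = {m: [] for m in models}
    # fit simpler models first so richer nested models can warm-start
    # from the embedded solution of their parent (as restart 0)
    fit_order = sorted(models, key=lambda m: (MODEL_SPECS[m].k, m))
    i = 0
    for m in fit_order:
        for j, subj in enumerate(subjects):
            rng = np.random.default_rng(children[i])
            i += 1
            warm = []
            for src in fit_order:
                if fits.get(src) and len(fits[src]) > j:
                    lifted = embed_params(m, src, fits[src][j].params)
                    if lifted is not None:
                        warm.append(lifted)
            fits[m].append(
                fit_subject(
                    m, logs[subj], n_restarts=n_restarts, seed=rng,
                    subject=subj, init_params=warm or None, **fit_kwargs,
                )
            )
    rows = []
    base_fits = fits[base_model]
    for m in models:
        sum_bic = sum(f.bic for f in fits[m])
        log10_bf = log10_group_bayes_factor(base_fits, fits[m])
        rows.append(
            {
                "model": m,
                "k": MODEL_SPECS[m].k,
                "sum_bic": sum_bic,
                "log10_bf_vs_base": log10_bf,
                "bf_vs_base": 10.0 ** log10_bf if log10_bf < 300 else math.inf,
            }
        )
    table = pd.DataFrame(rows).sort_values("sum_bic").reset_index(drop=True)
    best = table.iloc[0]["model"]
    top2 = list(table["model"].iloc[:2])
    paired = pd.DataFrame(
        {
            "subject": subjects,
            **{
                m: [f.nll for f in fits[m]] for m in top2
            },
        }
    )
    return ComparisonResult(table, best, fits, paired)
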