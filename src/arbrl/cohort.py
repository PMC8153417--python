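"""Synthetic cohorts with depression-linked parameters, and recovery analyses.

The cohort generator stands in for a human sample: each synthetic subject
gets a CES-D depression score (0-60 scale, subclinical cutoff 16) and a
set of true model parameters.  Two parameters carry the depression effect
through monotone noisy links — the model-free reliability learning rate
eta rises with CES-D, and the model-based exploitation weight tau_mb
falls — while all other parameters are drawn independently of the score.

On top of the generator sit the three recovery analyses (parameter, model,
and behavior recovery) and the end-to-end depression-effect replication
pipeline: sample -> simulate -> measure -> fit -> correlate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _engine
from .arbitration import ArbConfig
from .fitting import (
    MODEL_SPECS,
    FitResult,
    compare_models,
    encode_graph,
    fit_subject,
)
from .measures import (
    IdealAgent,
    accumulated_reward,
    choice_consistency,
    choice_optimality,
    correlate_with_score,
)
from .task import TaskConfig, make_block_schedule

CESD_CUTOFF = 16


@dataclass(frozen=True)
class EffectLinks:
    """Monotone CES-D -> parameter links on transformed scales.

    eta is linear in the normalized score on the log-odds scale (sigmoid
    keeps it in (0, 1)); tau_mb is linear on the log scale between a high
    (score 0) and low (score max) anchor.  Gaussian noise is added on the
    transformed scale before mapping back.
    """

    eta_intercept: float = -2.0
    eta_slope: float = 2.5          # log-odds change over the full score range
    eta_noise: float = 0.35
    tau_mb_high: float = 1.2        # tau_mb anchor at score 0
    tau_mb_low: float = 0.02        # tau_mb anchor at the top of the range
    tau_mb_noise: float = 0.25      # sd on the log scale

    @staticmethod
    def null() -> "EffectLinks":
        """Zero-slope links: parameters independent of the score."""
        return EffectLinks(eta_slope=0.0, tau_mb_low=0.2, tau_mb_high=0.2)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of one synthetic cohort."""

    n_subjects: int = 30
    model: str = "Arb_a_t3"
    cesd_low: int = 0
    cesd_high: int = 40             # uniform integers; both cutoff sides occupied
    links: EffectLinks = field(default_factory=EffectLinks)
    task: TaskConfig = field(default_factory=TaskConfig)
    seed: int = 0
    pretraining_rewarded: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.cesd_low <= self.cesd_high <= 60):
            raise ValueError("CES-D range must lie within [0, 60]")
        if self.model not in MODEL_SPECS:
            raise ValueError(f"unknown model {self.model!r}")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# independent priors for parameters not driven by the depression links
def _draw_param(name: str, rng: np.random.Generator) -> float:
    if name in ("alpha", "alpha_mb", "alpha_mf"):
        return float(rng.beta(2.0, 2.0))
    if name == "A_beta":
        # beta sees chi_MF (typically ~0.7) through 1/(1+e^{B chi}); the
        # larger amplitude keeps the MF->MB rate comparable to gamma's
        return float(rng.uniform(6.0, 10.0))
    if name == "A_gamma":
        return float(rng.uniform(0.6, 2.4))
    if name in ("tau", "tau_mf"):
        return float(np.exp(rng.normal(math.log(0.15), 0.25)))
    if name == "c":
        return float(np.exp(rng.normal(math.log(0.4), 0.3)))
    if name == "c1":
        return float(np.exp(rng.normal(math.log(0.05), 0.3)))
    if name == "c2":
        raise KeyError("c2 is derived from c1")
    if name == "c3":
        return float(rng.uniform(5.0, 15.0))
    if name == "c4":
        return float(rng.uniform(0.3, 0.7))
    raise KeyError(f"no prior for parameter {name!r}")


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Seeded draw of (subject, CES-D score, true parameters).

    eta and tau_mb follow the effect links when the model has them; every
    other parameter is drawn from its independent prior.
    """
    rng = np.random.default_rng(spec.seed)
    model = MODEL_SPECS[spec.model]
    links = spec.links
    span = max(spec.cesd_high - spec.cesd_low, 1)
    rows = []
    for i in range(spec.n_subjects):
        cesd = int(rng.integers(spec.cesd_low, spec.cesd_high + 1))
        c = (cesd - spec.cesd_low) / span
        params: dict[str, float] = {}
        for name in model.param_names:
            if name == "eta":
                z = links.eta_intercept + links.eta_slope * c + rng.normal(
                    0.0, links.eta_noise
                )
                params[name] = _sigmoid(z)
            elif name == "tau_mb":
                z = (
                    math.log(links.tau_mb_high)
                    + c * (math.log(links.tau_mb_low) - math.log(links.tau_mb_high))
                    + rng.normal(0.0, links.tau_mb_noise)
                )
                params[name] = min(math.exp(z), 50.0)
            elif name == "c2":
                params["c2"] = params["c1"] + float(
                    np.exp(rng.normal(math.log(0.3), 0.3))
                )
            else:
                params[name] = _draw_param(name, rng)
        rows.append({"subject": f"sub{i:03d}", "cesd": cesd, **params})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    params: Mapping[str, float],
    task: TaskConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    model: str = "Arb_a_t3",
    subject: str = "subject",
    config: ArbConfig = ArbConfig(),
    pretraining_rewarded: bool = False,
    return_latents: bool = False,
):
    """Simulate one subject's full task run from true parameters.

    Produces the reward-free pre-training session (session 0) followed by
    the main sessions, as a standard trial-log DataFrame; latents use the
    same per-trial layout as the likelihood replay.
    """
    task = task or TaskConfig()
    spec = MODEL_SPECS[model]
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    sched_rng, u_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    sessions: list[tuple[int, bool, list[tuple[str, str]]]] = []
    n_pre = task.sessions.n_pretraining
    if n_pre > 0:
        pre = make_block_schedule(
            n_pre, sched_rng, colors=task.graph.colors
        ).trial_conditions()[:n_pre]
        sessions.append((0, True, pre))
    for s in range(1, task.sessions.n_sessions + 1):
        sched = make_block_schedule(
            task.sessions.session_trials_target, sched_rng,
            colors=task.graph.colors,
        )
        sessions.append((s, False, sched.trial_conditions()))

    graph = task.graph
    s1_succ, s2_succ, rtab, goal_idx = encode_graph(graph)
    goal_lab, unc_lab, sess_no, trial_no, is_pre_l = [], [], [], [], []
    for sess, pre_flag, conds in sessions:
        for t, (goal, unc) in enumerate(conds, start=1):
            goal_lab.append(goal)
            unc_lab.append(unc)
            sess_no.append(sess)
            trial_no.append(t)
            is_pre_l.append(pre_flag)
    n = len(goal_lab)
    is_pre = np.array(is_pre_l, dtype=np.uint8)
    goal = np.array([goal_idx[g] for g in goal_lab], dtype=np.int64)
    p_first = np.array(
        [task.transitions.first_successor_prob(u) for u in unc_lab]
    )
    u = u_rng.random((n, 4))
    a1 = np.empty(n, dtype=np.int64)
    s2 = np.empty(n, dtype=np.int64)
    a2 = np.empty(n, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    reward = np.empty(n, dtype=float)
    latents = np.empty((n, _engine.N_LATENTS))
    rpe_max = config.rpe_max if config.rpe_max is not None else graph.max_coin_value

    _engine.simulate(
        is_pre, goal, p_first, s1_succ, s2_succ, rtab,
        config.spe_zero_threshold, config.spe_window,
        config.spe_prior[0], config.spe_prior[1],
        rpe_max, config.rate_steepness,
        *spec.engine_args(params),
        pretraining_rewarded, config.p_mb_init,
        u, a1, s2, a2, out, reward, latents,
    )

    acts = np.array(["L", "R"])
    second = np.array(graph.second_stage_states)
    outcomes = np.array(graph.outcome_states)
    log = pd.DataFrame(
        {
            "subject_id": subject,
            "session": sess_no,
            "trial": trial_no,
            "is_pretraining": is_pre.astype(bool),
            "goal": goal_lab,
            "uncertainty": unc_lab,
            "s1": graph.first_stage_state,
            "a1": acts[a1],
            "s2": second[s2],
            "a2": acts[a2],
            "s_outcome": outcomes[out],
            "reward": reward,
        }
    )
    if return_latents:
        cols = [
            "spe1", "spe2", "rpe1", "rpe2", "chi_mb", "chi_mf", "p_mb",
            "tau1", "tau2", "p_chosen1", "p_chosen2", "p_right1", "p_right2",
        ]
        return log, pd.DataFrame(latents, columns=cols)
    return log


def simulate_cohort(
    cohort: pd.DataFrame,
    spec: CohortSpec,
) -> dict[str, pd.DataFrame]:
    """Simulate every subject of a sampled cohort; returns subject -> log."""
    ss = np.random.SeedSequence([spec.seed, 1])
    children = ss.spawn(len(cohort))
    param_names = MODEL_SPECS[spec.model].param_names
    logs = {}
    for child, row in zip(children, cohort.itertuples()):
        params = {p: getattr(row, p) for p in param_names}
        logs[row.subject] = simulate_subject(
            params, spec.task, child, model=spec.model, subject=row.subject,
            pretraining_rewarded=spec.pretraining_rewarded,
        )
    return logs


def cohort_measures(
    logs: Mapping[str, pd.DataFrame], task: TaskConfig | None = None
) -> pd.DataFrame:
    """Per-subject accumulated reward, choice optimality, choice consistency."""
    task = task or TaskConfig()
    ideal = IdealAgent(task.graph, task.transitions)
    rows = []
    for subj, log in logs.items():
        rows.append(
            {
                "subject": subj,
                "accumulated_reward": accumulated_reward(log),
                "choice_optimality": choice_optimality(log, ideal),
                "choice_consistency": choice_consistency(log),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery analyses
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Results of a parameter-recovery experiment."""

    correlations: pd.DataFrame      # parameter, spearman_r, p
    scatter: pd.DataFrame           # subject, parameter, true, fitted
    fits: list[FitResult]


def run_parameter_recovery(
    spec: CohortSpec,
    n_restarts: int = 32,
    seed: int = 0,
    inject_truth: bool = True,
    **fit_kwargs,
) -> RecoveryReport:
    """Simulate a cohort, refit each subject, correlate true vs fitted.

    The generating parameters are injected as restart 0 of each fit, so
    the optimizer can never return a worse likelihood than the truth's.
    """
    cohort = sample_cohort(spec)
    logs = simulate_cohort(cohort, spec)
    param_names = MODEL_SPECS[spec.model].param_names
    ss = np.random.SeedSequence([seed, 2])
    fits = []
    for child, row in zip(ss.spawn(len(cohort)), cohort.itertuples()):
        truth = {p: getattr(row, p) for p in param_names}
        fits.append(
            fit_subject(
                spec.model, logs[row.subject], n_restarts=n_restarts,
                seed=np.random.default_rng(child), subject=row.subject,
                graph=spec.task.graph,
                init_params=truth if inject_truth else None, **fit_kwargs,
            )
        )
    scatter_rows = []
    for row, fit in zip(cohort.itertuples(), fits):
        for p in param_names:
            scatter_rows.append(
                {
                    "subject": row.subject,
                    "parameter": p,
                    "true": getattr(row, p),
                    "fitted": fit.params[p],
                }
            )
    scatter = pd.DataFrame(scatter_rows)
    corr_rows = []
    for p in param_names:
        sub = scatter[scatter["parameter"] == p]
        r, pv = correlate_with_score(sub["fitted"], sub["true"], kind="spearman")
        corr_rows.append({"parameter": p, "spearman_r": r, "p": pv})
    return RecoveryReport(pd.DataFrame(corr_rows), scatter, fits)


def run_model_recovery(
    generating_model: str,
    spec: CohortSpec,
    candidates: Sequence[str] = tuple(MODEL_SPECS),
    n_reps: int = 5,
    n_restarts: int = 8,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Confusion counts: how often each candidate wins on regenerated data.

    Each repetition samples a fresh cohort from ``generating_model``,
    simulates it, runs the full model comparison, and records the group-BF
    winner.  Returns a one-row DataFrame (generator x winner counts).
    """
    if generating_model not in candidates:
        raise ValueError("generating model must be among the candidates")
    counts = {m: 0 for m in candidates}
    for rep in range(n_reps):
        rep_spec = replace(
            spec, model=generating_model, seed=spec.seed + 7919 * (rep + 1)
        )
        cohort = sample_cohort(rep_spec)
        logs = simulate_cohort(cohort, rep_spec)
        cmp = compare_models(
            logs, models=list(candidates), n_restarts=n_restarts,
            seed=rep_spec.seed, graph=rep_spec.task.graph, **fit_kwargs,
        )
        counts[cmp.best_model] += 1
    return pd.DataFrame([counts], index=[generating_model])


def run_behavior_recovery(
    fits: Sequence[FitResult],
    source_measures: pd.DataFrame,
    task: TaskConfig | None = None,
    n_reps: int = 100,
    seed: int = 0,
    model: str | None = None,
) -> dict:
    """Re-simulate each subject from fitted parameters; correlate measures.

    Each subject is replicated ``n_reps`` times with fresh seeds; the three
    behavioral measures are averaged over replications and correlated
    (Pearson) against the source cohort's measures across subjects.
    Undefined correlations (zero variance) are reported as NaN.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    task = task or TaskConfig()
    ideal = IdealAgent(task.graph, task.transitions)
    ss = np.random.SeedSequence([seed, 3])
    rows = []
    for child, fit in zip(ss.spawn(len(fits)), fits):
        vals = np.zeros(3)
        for rep_seed in child.spawn(n_reps):
            log = simulate_subject(
                fit.params, task, rep_seed, model=model or fit.model,
                subject=fit.subject,
            )
            vals += (
                accumulated_reward(log),
                choice_optimality(log, ideal),
                choice_consistency(log),
            )
        vals /= n_reps
        rows.append(
            {
                "subject": fit.subject,
                "accumulated_reward": vals[0],
                "choice_optimality": vals[1],
                "choice_consistency": vals[2],
            }
        )
    sim = pd.DataFrame(rows)
    merged = source_measures.merge(sim, on="subject", suffixes=("_src", "_sim"))
    result = {"simulated_measures": sim}
    for m in ("accumulated_reward", "choice_optimality", "choice_consistency"):
        src = merged[f"{m}_src"].to_numpy()
        rep = merged[f"{m}_sim"].to_numpy()
        if (
            len(src) < 4
            or np.isclose(src.var(), 0.0)
            or np.isclose(rep.var(), 0.0)
        ):
            # undefined: too few subjects or no between-subject variance
            result[m] = {"r": float("nan"), "p": float("nan")}
        else:
            r, p = correlate_with_score(rep, src, kind="pearson")
            result[m] = {"r": r, "p": p}
    return result


# ---------------------------------------------------------------------------
# depression-effect replication
# ---------------------------------------------------------------------------

def run_depression_effect_report(
    spec: CohortSpec,
    n_restarts: int = 16,
    seed: int = 0,
    fit_model: str = "Arb_a_t3",
    **fit_kwargs,
) -> dict:
    """End-to-end sign-level replication of the depression effects.

    Pipeline: sample a cohort -> simulate -> behavioral measures -> fit ->
    correlate.  Reports Pearson correlations of CES-D with the three
    behavioral measures (expected negative with default links), Spearman
    correlations of CES-D with the fitted eta (expected positive) and
    tau_mb (expected negative), and the group split at the CES-D cutoff.
    """
    cohort = sample_cohort(spec)
    logs = simulate_cohort(cohort, spec)
    meas = cohort_measures(logs, spec.task).merge(
        cohort[["subject", "cesd"]], on="subject"
    )

    report: dict = {"n_subjects": len(cohort)}
    for m in ("accumulated_reward", "choice_optimality", "choice_consistency"):
        r, p = correlate_with_score(meas[m], meas["cesd"], kind="pearson")
        report[f"cesd_vs_{m}"] = {"r": r, "p": p}

    ss = np.random.SeedSequence([seed, 4])
    fits = []
    for child, subj in zip(ss.spawn(len(cohort)), cohort["subject"]):
        fits.append(
            fit_subject(
                fit_model, logs[subj], n_restarts=n_restarts,
                seed=np.random.default_rng(child), subject=subj,
                graph=spec.task.graph, **fit_kwargs,
            )
        )
    fitted = pd.DataFrame(
        [{"subject": f.subject, **{k: v for k, v in f.params.items()}} for f in fits]
    ).merge(cohort[["subject", "cesd"]], on="subject")
    for pname in ("eta", "tau_mb"):
        if pname in fitted:
            r, p = correlate_with_score(
                fitted[pname], fitted["cesd"], kind="spearman"
            )
            report[f"cesd_vs_fitted_{pname}"] = {"rho": r, "p": p}

    sub = meas[meas["cesd"] >= CESD_CUTOFF]
    healthy = meas[meas["cesd"] < CESD_CUTOFF]
    if len(sub) == 0:
        raise ValueError("subclinical group empty")
    if len(healthy) == 0:
        raise ValueError("healthy group empty")
    report["group_means"] = {
        "healthy": healthy[
            ["accumulated_reward", "choice_optimality", "choice_consistency"]
        ].mean().to_dict(),
        "subclinical": sub[
            ["accumulated_reward", "choice_optimality", "choice_consistency"]
        ].mean().to_dict(),
        "n_healthy": int(len(healthy)),
        "n_subclinical": int(len(sub)),
    }
    report["measures"] = meas
    report["fitted"] = fitted
    report["fits"] = fits
    return report
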