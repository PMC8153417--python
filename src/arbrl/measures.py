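"""Model-free behavioral measures and descriptive analyses.

Three per-subject read-outs summarize choice behavior without fitting any
learning model: accumulated reward (overall performance), choice
optimality (agreement with an omniscient ideal agent; a read-out of
goal-directed control), and first-stage choice consistency (a read-out of
habitual control).  Calibration curves, goal-by-uncertainty condition
breakdowns, and score correlations support the cohort-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .task import (
    ACTIONS,
    TaskGraph,
    TransitionSetting,
    build_task_graph,
    goal_reward,
)


def _goal_kind(goal: str) -> str:
    return "flexible" if goal == "flexible" else "specific"


@dataclass(frozen=True)
class IdealAgent:
    """Greedy planner with full, immediate access to the true environment.

    Knows the true transition probabilities of each uncertainty condition
    and the current goal, plans exact expected values, and splits ties
    uniformly.  Its policy probability of a subject's chosen action is the
    per-decision optimality score (1 for the unique best action, 1/2 under
    a two-way tie, 0 otherwise).
    """

    graph: TaskGraph = field(default_factory=build_task_graph)
    transitions: TransitionSetting = field(default_factory=TransitionSetting)
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def q_values(
        self, goal: str, uncertainty: str
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """(first-stage Q over L/R, second-stage Q per state over L/R)."""
        key = (goal, uncertainty)
        if key in self._cache:
            return self._cache[key]
        p = self.transitions.first_successor_prob(uncertainty)
        w = (p, 1.0 - p)
        q2: dict[str, np.ndarray] = {}
        for s in self.graph.second_stage_states:
            q2[s] = np.array(
                [
                    sum(
                        wi * goal_reward(sp, goal, self.graph)
                        for wi, sp in zip(w, self.graph.successors(s, a))
                    )
                    for a in ACTIONS
                ]
            )
        q1 = np.array(
            [
                sum(
                    wi * q2[sp].max()
                    for wi, sp in zip(
                        w, self.graph.successors(self.graph.first_stage_state, a)
                    )
                )
                for a in ACTIONS
            ]
        )
        self._cache[key] = (q1, q2)
        return q1, q2

    def policy_prob(
        self, state: str, action: str, goal: str, uncertainty: str
    ) -> float:
        q1, q2 = self.q_values(goal, uncertainty)
        q = q1 if state == self.graph.first_stage_state else q2[state]
        best = q.max()
        argmax = np.isclose(q, best, rtol=0.0, atol=1e-12)
        i = ACTIONS.index(action)
        return float(argmax[i]) / argmax.sum()


def _main_trials(log: pd.DataFrame) -> pd.DataFrame:
    if len(log) == 0:
        raise ValueError("empty trial log")
    return log[~log["is_pretraining"].astype(bool)]


def accumulated_reward(log: pd.DataFrame) -> float:
    """Total points over the main (non-pretraining) sessions."""
    return float(_main_trials(log)["reward"].sum())


def _optimality_scores(log: pd.DataFrame, ideal: IdealAgent) -> pd.DataFrame:
    main = _main_trials(log)
    rows = []
    for t in main.itertuples():
        for state, action in ((t.s1, t.a1), (t.s2, t.a2)):
            rows.append(
                {
                    "goal_kind": _goal_kind(t.goal),
                    "uncertainty": t.uncertainty,
                    "score": ideal.policy_prob(state, action, t.goal, t.uncertainty),
                }
            )
    return pd.DataFrame(rows)


def choice_optimality(
    log: pd.DataFrame, ideal: IdealAgent | None = None, by_condition: bool = False
):
    """Mean ideal-agent likelihood of the subject's actual choices.

    Both decisions of every main trial are scored; chance level is 0.5 for
    the binary states (tie-splitting corrects for the number of options).
    """
    ideal = ideal or IdealAgent()
    scores = _optimality_scores(log, ideal)
    if by_condition:
        return scores.groupby(["goal_kind", "uncertainty"])["score"].mean()
    return float(scores["score"].mean())


def choice_consistency(log: pd.DataFrame, by_condition: bool = False):
    """Proportion of first-stage choices repeating the previous trial's.

    Computed within sessions only (no carry-over across session
    boundaries); trial t >= 2 scores 1 when a1(t) == a1(t-1).
    """
    main = _main_trials(log)
    if len(main) < 2:
        raise ValueError("need at least 2 main trials")
    rows = []
    for _, sess in main.groupby("session", sort=True):
        a1 = sess["a1"].to_numpy()
        same = a1[1:] == a1[:-1]
        for i, rep in enumerate(same, start=1):
            t = sess.iloc[i]
            rows.append(
                {
                    "goal_kind": _goal_kind(t["goal"]),
                    "uncertainty": t["uncertainty"],
                    "score": float(rep),
                }
            )
    scores = pd.DataFrame(rows)
    if by_condition:
        return scores.groupby(["goal_kind", "uncertainty"])["score"].mean()
    return float(scores["score"].mean())


def calibration_curve(
    p_right: np.ndarray, chose_right: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Empirical proportion of right choices per model-probability bin.

    Bins partition [0, 1]; empty bins are kept with ``count`` 0 and NaN
    proportions so the table shape is stable.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p_right = np.asarray(p_right, dtype=float)
    chose_right = np.asarray(chose_right, dtype=float)
    if np.any((p_right < 0) | (p_right > 1)):
        raise ValueError("probabilities outside [0,1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p_right, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "count": int(mask.sum()),
                "mean_predicted": float(p_right[mask].mean()) if mask.any() else np.nan,
                "prop_right": float(chose_right[mask].mean()) if mask.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def condition_breakdown(per_trial: pd.DataFrame, value_col: str = "score") -> dict:
    """2x2 (goal kind x uncertainty) cell means and factorial F tests.

    ``per_trial`` needs columns ``goal_kind``, ``uncertainty`` and the
    value column.  F statistics come from a type-II two-way ANOVA with
    interaction; with no residual variance the F's are reported as 0.
    """
    cells = per_trial.groupby(["goal_kind", "uncertainty"])[value_col]
    counts = cells.count()
    if len(counts) < 4 or (counts == 0).any():
        raise ValueError("all four goal x uncertainty cells must be occupied")
    means = cells.mean()

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = per_trial.rename(columns={value_col: "y"})[
        ["y", "goal_kind", "uncertainty"]
    ].copy()
    if np.isclose(df["y"].var(ddof=1), 0.0):
        f = {"goal": 0.0, "uncertainty": 0.0, "interaction": 0.0}
        p = {k: 1.0 for k in f}
    else:
        fit = smf.ols("y ~ C(goal_kind) * C(uncertainty)", data=df).fit()
        try:
            anova = sm.stats.anova_lm(fit, typ=2)
        except ValueError:
            anova = sm.stats.anova_lm(fit, typ=1)
        def _get(term, col):
            v = float(anova.loc[term, col])
            return 0.0 if not np.isfinite(v) else v
        f = {
            "goal": _get("C(goal_kind)", "F"),
            "uncertainty": _get("C(uncertainty)", "F"),
            "interaction": _get("C(goal_kind):C(uncertainty)", "F"),
        }
        p = {
            "goal": _get("C(goal_kind)", "PR(>F)"),
            "uncertainty": _get("C(uncertainty)", "PR(>F)"),
            "interaction": _get("C(goal_kind):C(uncertainty)", "PR(>F)"),
        }
    return {"cell_means": means, "F": f, "p": p}


def correlate_with_score(values, scores, kind: str = "pearson") -> tuple[float, float]:
    """Correlation (and two-sided p) between per-subject values and scores.

    Pearson for behavioral measures; Spearman for fitted parameters, which
    are right-skewed by their lower bound at zero.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(values) != len(scores):
        raise ValueError("length mismatch")
    if len(values) < 4:
        raise ValueError("need at least 4 subjects")
    if np.isclose(values.var(), 0.0) or np.isclose(scores.var(), 0.0):
        raise ValueError("zero variance input")
    if kind == "pearson":
        r, p = stats.pearsonr(values, scores)
    elif kind == "spearman":
        r, p = stats.spearmanr(values, scores)
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    return float(r), float(p)
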