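"""The two value-learning systems.

The model-based (FORWARD) learner maintains a state-action-state transition
model updated from state prediction errors and plans action values by
backward induction through the task graph under the current goal.  The
model-free learner caches state-action values with SARSA, driven by reward
prediction errors, and is deliberately insensitive to goal changes: its
values are never re-planned, only incrementally updated from realized
goal-conditional rewards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .task import TaskGraph, goal_reward


@dataclass(frozen=True)
class TransitionModel:
    """Learned transition probabilities T(s, a, s') with learning rate kappa.

    Probabilities for each (state, action) are stored as an array aligned
    with the graph's ordered successor pair.
    """

    graph: TaskGraph
    probs: Mapping[tuple[str, str], np.ndarray]
    kappa: float = 0.2

    @staticmethod
    def uniform(graph: TaskGraph, kappa: float = 0.2) -> "TransitionModel":
        """Uninformative start: each successor pair equally likely."""
        probs = {
            key: np.full(len(succ), 1.0 / len(succ))
            for key, succ in graph.successor_map.items()
        }
        return TransitionModel(graph, probs, kappa)

    def prob(self, s: str, a: str, s_next: str) -> float:
        succ = self.graph.successors(s, a)
        if s_next not in succ:
            raise KeyError(f"{s_next} is not a successor of ({s},{a})")
        return float(self.probs[(s, a)][succ.index(s_next)])


@dataclass(frozen=True)
class MBValues:
    """Planned (goal-sensitive) action values of the model-based system."""

    q: Mapping[tuple[str, str], float]

    def value(self, s: str, a: str) -> float:
        return self.q[(s, a)]


@dataclass(frozen=True)
class MFValues:
    """Cached SARSA action values of the model-free system."""

    q: Mapping[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = 0.2

    def value(self, s: str, a: str) -> float:
        return self.q.get((s, a), 0.0)

    @staticmethod
    def zeros(alpha: float = 0.2) -> "MFValues":
        return MFValues({}, alpha)


def state_prediction_error(
    T: TransitionModel, s: str, a: str, s_next: str
) -> float:
    """SPE = 1 - predicted probability of the observed transition."""
    return 1.0 - T.prob(s, a, s_next)


def update_transition_model(
    T: TransitionModel, s: str, a: str, s_observed: str
) -> TransitionModel:
    """Move the observed successor toward 1 and its siblings toward 0.

    The observed entry gains kappa*(1 - T); every unobserved successor of
    the same (s, a) decays by kappa*T, which keeps the row normalized.
    """
    if not 0.0 <= T.kappa <= 1.0:
        raise ValueError(f"kappa={T.kappa} outside [0,1]")
    succ = T.graph.successors(s, a)
    if s_observed not in succ:
        raise KeyError(f"{s_observed} is not a successor of ({s},{a})")
    row = T.probs[(s, a)].copy()
    for i, sp in enumerate(succ):
        target = 1.0 if sp == s_observed else 0.0
        row[i] += T.kappa * (target - row[i])
    probs = dict(T.probs)
    probs[(s, a)] = row
    return replace(T, probs=probs)


def plan_mb_values(
    T: TransitionModel, graph: TaskGraph, goal: str
) -> MBValues:
    """Backward induction through the two-stage graph under ``goal``.

    Q(s, a) = sum_{s'} T(s, a, s') * (r(s') + max_{a'} Q(s', a')), with
    r(s') nonzero only at outcome states (where it is the goal-conditional
    coin value) and outcome states terminal.
    """
    q: dict[tuple[str, str], float] = {}

    # second stage first: successors are outcomes
    for s in graph.second_stage_states:
        for a in ("L", "R"):
            succ = graph.successors(s, a)
            row = T.probs[(s, a)]
            q[(s, a)] = float(
                sum(p * goal_reward(sp, goal, graph) for p, sp in zip(row, succ))
            )

    s1 = graph.first_stage_state
    for a in ("L", "R"):
        succ = graph.successors(s1, a)
        row = T.probs[(s1, a)]
        q[(s1, a)] = float(
            sum(p * max(q[(sp, "L")], q[(sp, "R")]) for p, sp in zip(row, succ))
        )
    return MBValues(q)


def sarsa_update(
    Q: MFValues,
    s: str,
    a: str,
    r: float,
    s_next: str | None,
    a_next: str | None,
) -> tuple[MFValues, float]:
    """One SARSA step; returns the updated values and the RPE.

    RPE = r + Q(s', a') - Q(s, a), with the bootstrap term zero at terminal
    states (outcome states end the trial).
    """
    if not 0.0 <= Q.alpha <= 1.0:
        raise ValueError(f"alpha={Q.alpha} outside [0,1]")
    if (s_next is None) != (a_next is None):
        raise ValueError("a_next must be given exactly when s_next is")
    bootstrap = 0.0 if s_next is None else Q.value(s_next, a_next)
    rpe = r + bootstrap - Q.value(s, a)
    q = dict(Q.q)
    q[(s, a)] = Q.value(s, a) + Q.alpha * rpe
    return replace(Q, q=q), float(rpe)
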