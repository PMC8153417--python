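"""Two-stage Markov decision task: state graph, goals, transitions, blocks.

The task is a sequential decision problem: from a fixed start state the
agent makes a binary choice (left/right), transitions probabilistically to
one of four second-stage states, chooses again, and lands in an outcome
state carrying a colored coin.  Reward depends on the trial's goal
condition: under a *flexible* goal every coin pays its face value; under a
*specific(color)* goal only matching coins pay.  Transition noise is
blockwise: low-uncertainty blocks use a (0.9, 0.1) split over the two
successors of each (state, action), high-uncertainty blocks use (0.5, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ACTIONS = ("L", "R")

#: default coin colors; values are points, overridable in any config
DEFAULT_COIN_VALUES = {"red": 40.0, "blue": 20.0, "yellow": 10.0}

#: default coin color of each of the eight outcome states O1..O8
DEFAULT_OUTCOME_COLORS = (
    "red", "yellow",   # successors of S2
    "blue", "red",     # successors of S3
    "yellow", "blue",  # successors of S4
    "red", "yellow",   # successors of S5
)

#: transition probability of the *first* successor, per uncertainty level
DEFAULT_TRANSITIONS = {"low": (0.9, 0.1), "high": (0.5, 0.5)}

FLEXIBLE = "flexible"


def specific(color: str) -> str:
    """Goal label for the specific-goal condition with the given coin color."""
    return f"specific:{color}"


def goal_color(goal: str) -> str | None:
    """Color of a specific goal, or None for the flexible goal."""
    if goal == FLEXIBLE:
        return None
    if goal.startswith("specific:"):
        return goal.split(":", 1)[1]
    raise ValueError(f"unknown goal label {goal!r}")


class TaskConfigError(ValueError):
    """Raised when a task configuration is internally inconsistent."""


@dataclass(frozen=True)
class TransitionSetting:
    """Probability of the first-listed successor per uncertainty condition."""

    probabilities: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )

    def __post_init__(self) -> None:
        for cond, pair in self.probabilities.items():
            if len(pair) != 2:
                raise TaskConfigError(f"{cond}: need a probability pair")
            if not all(0.0 <= p <= 1.0 for p in pair):
                raise TaskConfigError(f"{cond}: probabilities outside [0,1]")
            if abs(sum(pair) - 1.0) > 1e-9:
                raise TaskConfigError(f"{cond}: pair must sum to 1")

    def first_successor_prob(self, uncertainty: str) -> float:
        return self.probabilities[uncertainty][0]


@dataclass(frozen=True)
class TaskGraph:
    """The two-stage state/action structure with coin assignments.

    ``successor_map`` maps every non-terminal (state, action) to an ordered
    pair of successors; the transition setting assigns probability ``p`` to
    the first of the pair.
    """

    first_stage_state: str
    second_stage_states: tuple[str, ...]
    outcome_colors: Mapping[str, str]          # outcome state -> coin color
    successor_map: Mapping[tuple[str, str], tuple[str, str]]
    coin_values: Mapping[str, float]

    def __post_init__(self) -> None:
        for (s, a), succ in self.successor_map.items():
            if len(succ) != 2:
                raise TaskConfigError(
                    f"successor pair of ({s},{a}) has arity {len(succ)}, expected 2"
                )
        for out, color in self.outcome_colors.items():
            if color not in self.coin_values:
                raise TaskConfigError(
                    f"outcome {out} has color {color!r} with no configured coin value"
                )
        for color, v in self.coin_values.items():
            if v < 0:
                raise TaskConfigError(f"coin value for {color!r} is negative")

    @property
    def outcome_states(self) -> tuple[str, ...]:
        return tuple(self.outcome_colors)

    @property
    def colors(self) -> tuple[str, ...]:
        return tuple(self.coin_values)

    @property
    def max_coin_value(self) -> float:
        return max(self.coin_values.values())

    def successors(self, state: str, action: str) -> tuple[str, str]:
        try:
            return self.successor_map[(state, action)]
        except KeyError:
            raise KeyError(f"({state},{action}) has no successors") from None

    def is_outcome(self, state: str) -> bool:
        return state in self.outcome_colors

    def decision_states(self) -> tuple[str, ...]:
        return (self.first_stage_state,) + self.second_stage_states


def build_task_graph(config: Mapping | None = None) -> TaskGraph:
    """Build (and validate) a task graph from a configuration mapping.

    Recognised keys: ``coin_values`` (color -> points), ``outcome_colors``
    (sequence of 8 colors for O1..O8, or mapping outcome -> color), and
    ``successor_map`` for fully custom layouts.  Omitted keys fall back to
    the default layout: one start state S1, four second-stage states S2..S5
    reachable as the left pair (S2, S3) and right pair (S4, S5), and eight
    outcome states; within a second-stage state the two actions share the
    same outcome pair with reversed transition order.
    """
    config = dict(config or {})
    coin_values = {
        str(k): float(v)
        for k, v in config.get("coin_values", DEFAULT_COIN_VALUES).items()
    }

    if "successor_map" in config:
        succ = {
            (s, a): tuple(v) for (s, a), v in config["successor_map"].items()
        }
        outcome_colors = dict(config["outcome_colors"])
        first = config.get("first_stage_state", "S1")
        second = tuple(config.get("second_stage_states", ()))
        return TaskGraph(first, second, outcome_colors, succ, coin_values)

    colors = config.get("outcome_colors", DEFAULT_OUTCOME_COLORS)
    if isinstance(colors, Mapping):
        outcome_colors = dict(colors)
        outcomes = tuple(outcome_colors)
    else:
        colors = tuple(colors)
        if len(colors) != 8:
            raise TaskConfigError(
                f"default layout needs 8 outcome colors, got {len(colors)}"
            )
        outcomes = tuple(f"O{i + 1}" for i in range(8))
        outcome_colors = dict(zip(outcomes, colors))

    second = ("S2", "S3", "S4", "S5")
    succ: dict[tuple[str, str], tuple[str, str]] = {
        ("S1", "L"): ("S2", "S3"),
        ("S1", "R"): ("S4", "S5"),
    }
    for i, s in enumerate(second):
        pair = (outcomes[2 * i], outcomes[2 * i + 1])
        succ[(s, "L")] = pair
        succ[(s, "R")] = (pair[1], pair[0])
    return TaskGraph("S1", second, outcome_colors, succ, coin_values)


def goal_reward(outcome_state: str, goal: str, graph: TaskGraph) -> float:
    """Points delivered in ``outcome_state`` under the trial's goal."""
    if not graph.is_outcome(outcome_state):
        raise ValueError(f"{outcome_state!r} is not an outcome state")
    color = graph.outcome_colors[outcome_state]
    value = graph.coin_values[color]
    gcolor = goal_color(goal)
    if gcolor is None:  # flexible: every coin redeemable
        return value
    return value if color == gcolor else 0.0


def sample_transition(
    state: str,
    action: str,
    uncertainty: str,
    rng: np.random.Generator,
    graph: TaskGraph,
    transitions: TransitionSetting | None = None,
) -> str:
    """Draw the successor of (state, action) under the block's uncertainty."""
    transitions = transitions or TransitionSetting()
    first, second = graph.successors(state, action)
    p = transitions.first_successor_prob(uncertainty)
    return first if rng.random() < p else second


# ---------------------------------------------------------------------------
# block schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    goal: str           # "flexible" or "specific:<color>"
    uncertainty: str    # "low" | "high"
    n_trials: int


@dataclass(frozen=True)
class BlockSchedule:
    blocks: tuple[Block, ...]

    @property
    def n_trials(self) -> int:
        return sum(b.n_trials for b in self.blocks)

    def trial_conditions(self) -> list[tuple[str, str]]:
        """Flat per-trial (goal, uncertainty) sequence."""
        out: list[tuple[str, str]] = []
        for b in self.blocks:
            out.extend([(b.goal, b.uncertainty)] * b.n_trials)
        return out


LOW_BLOCK_LENGTHS = (3, 4, 5)
HIGH_BLOCK_LENGTHS = (5, 6, 7)

_CONDITION_TYPES = (
    ("flexible", "low"),
    ("flexible", "high"),
    ("specific", "low"),
    ("specific", "high"),
)


def make_block_schedule(
    n_trials_target: int,
    seed: int | np.random.Generator,
    colors: Sequence[str] = tuple(DEFAULT_COIN_VALUES),
) -> BlockSchedule:
    """Pseudo-random block schedule totalling at least ``n_trials_target``.

    Condition types (goal kind x uncertainty) are drawn uniformly with the
    constraint that the same type never occurs more than twice in a row;
    block lengths are uniform on 3-5 (low uncertainty) or 5-7 (high);
    specific-goal blocks get a uniformly drawn coin color.
    """
    if n_trials_target <= 0:
        raise ValueError("n_trials_target must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    blocks: list[Block] = []
    history: list[tuple[str, str]] = []
    total = 0
    while total < n_trials_target:
        while True:
            ctype = _CONDITION_TYPES[rng.integers(len(_CONDITION_TYPES))]
            if len(history) < 2 or not (history[-1] == history[-2] == ctype):
                break
        history.append(ctype)
        kind, uncertainty = ctype
        lengths = LOW_BLOCK_LENGTHS if uncertainty == "low" else HIGH_BLOCK_LENGTHS
        n = int(lengths[rng.integers(len(lengths))])
        goal = FLEXIBLE if kind == "flexible" else specific(
            colors[rng.integers(len(colors))]
        )
        blocks.append(Block(goal, uncertainty, n))
        total += n
    return BlockSchedule(tuple(blocks))


# ---------------------------------------------------------------------------
# trials and session structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    """One completed trial; the atomic unit of logs and likelihoods."""

    session: int
    trial: int
    goal: str
    uncertainty: str
    s1: str
    a1: str
    s2: str
    a2: str
    s_outcome: str
    reward: float
    is_pretraining: bool = False

    def validate(self, graph: TaskGraph) -> None:
        if self.s2 not in graph.successors(self.s1, self.a1):
            raise ValueError(
                f"trial {self.session}/{self.trial}: s2={self.s2} is not a "
                f"successor of ({self.s1},{self.a1})"
            )
        if self.s_outcome not in graph.successors(self.s2, self.a2):
            raise ValueError(
                f"trial {self.session}/{self.trial}: outcome={self.s_outcome} "
                f"is not a successor of ({self.s2},{self.a2})"
            )


@dataclass(frozen=True)
class SessionStructure:
    """Pre-training plus main-session layout of one subject's task run."""

    n_pretraining: int = 100
    n_sessions: int = 4
    session_trials_target: int = 80


@dataclass(frozen=True)
class TaskConfig:
    """Everything needed to instantiate one subject's task."""

    graph: TaskGraph = field(default_factory=build_task_graph)
    transitions: TransitionSetting = field(default_factory=TransitionSetting)
    sessions: SessionStructure = field(default_factory=SessionStructure)

    @staticmethod
    def from_mapping(cfg: Mapping) -> "TaskConfig":
        graph = build_task_graph(cfg.get("graph"))
        trans = TransitionSetting(
            {
                k: tuple(v)
                for k, v in cfg.get("transitions", DEFAULT_TRANSITIONS).items()
            }
        )
        s = cfg.get("sessions", {})
        sessions = SessionStructure(
            n_pretraining=int(s.get("n_pretraining", 100)),
            n_sessions=int(s.get("n_sessions", 4)),
            session_trials_target=int(s.get("session_trials_target", 80)),
        )
        return TaskConfig(graph, trans, sessions)
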