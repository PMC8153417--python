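from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arbrl.cohort import simulate_subject
from arbrl.task import SessionStructure, TaskConfig, build_task_graph

T3_PARAMS = {
    "alpha_mb": 0.5,
    "alpha_mf": 0.4,
    "eta": 0.3,
    "A_beta": 1.2,
    "A_gamma": 0.8,
    "tau_mb": 0.3,
    "tau_mf": 0.12,
}


@pytest.fixture(scope="session")
def graph():
    return build_task_graph()

@pytest.fixture(scope="session")
def short_task():
    """Reduced task (20 pre-training trials, 2 sessions of ~30) for fast fits."""
    return TaskConfig(sessions=SessionStructure(20, 2, 30))


@pytest.fixture(scope="session")
def t3_params():
    return dict(T3_PARAMS)


@pytest.fixture(scope="session")
def sim_log(t3_params):
    """One full-length simulated subject under the weighted-tau model."""
    return simulate_subject(t3_params, seed=11)


@pytest.fixture(scope="session")
def short_log(t3_params, short_task):
    return simulate_subject(t3_params, short_task, seed=12)


def random_params(rng: np.random.Generator, model: str) -> dict[str, float]:
    """Random in-bounds parameters for any model variant."""
    p = {
        "alpha_mb": rng.uniform(0.05, 0.95),
        "alpha_mf": rng.uniform(0.05, 0.95),
        "eta": rng.uniform(0.05, 0.95),
        "A_beta": rng.uniform(0.1, 3.0),
        "A_gamma": rng.uniform(0.1, 3.0),
    }
    if model == "Arb":
        p = {"alpha": rng.uniform(0.05, 0.95), **{k: p[k] for k in ("eta", "A_beta", "A_gamma")}}
        p["tau"] = rng.uniform(0.01, 0.5)
    elif model == "Arb_a":
        p["tau"] = rng.uniform(0.01, 0.5)
    elif model == "Arb_a_t1":
        c1 = rng.uniform(0.01, 0.2)
        p.update(c1=c1, c2=c1 + rng.uniform(0.05, 0.5),
                 c3=rng.uniform(2.0, 15.0), c4=rng.uniform(0.2, 0.8))
    elif model == "Arb_a_t2":
        p["c"] = rng.uniform(0.05, 0.8)
    elif model == "Arb_a_t3":
        p.update(tau_mb=rng.uniform(0.01, 0.6), tau_mf=rng.uniform(0.01, 0.6))
    else:
        raise ValueError(model)
    return p


def make_log(rows: list[dict]) -> pd.DataFrame:
    """Assemble a minimal trial-log DataFrame from partial row dicts."""
    defaults = {
        "subject_id": "s1",
        "session": 1,
        "is_pretraining": False,
        "goal": "flexible",
        "uncertainty": "low",
        "s1": "S1",
        "a1": "L",
        "s2": "S2",
        "a2": "L",
        "s_outcome": "O1",
        "reward": 40.0,
    }
    full = []
    for i, r in enumerate(rows, start=1):
        full.append({**defaults, "trial": i, **r})
    return pd.DataFrame(full)
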