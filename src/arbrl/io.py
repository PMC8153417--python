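"""File formats: trial-log CSV, fit-result JSON, configs, run outputs.

One CSV dialect is used throughout (comma, UTF-8, header required), with
actions as symbolic labels (L/R) and states as string ids to avoid 0/1
coding ambiguity.  Numbers are serialized at full precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .fitting import FitResult
from .task import TaskConfig, TaskGraph, build_task_graph

LOG_COLUMNS = [
    "subject_id", "session", "trial", "is_pretraining", "goal", "uncertainty",
    "s1", "a1", "s2", "a2", "s_outcome", "reward",
]


class TrialLogError(ValueError):
    """Raised for malformed or internally inconsistent trial logs."""


def read_trial_log(
    path: str | Path, graph: TaskGraph | None = None
) -> dict[str, pd.DataFrame]:
    """Read and validate a trial-log CSV; returns subject -> ordered log.

    Validation covers the schema, duplicate (subject, session, trial)
    keys, and transition consistency against the task graph; errors name
    the offending CSV row.
    """
    graph = graph or build_task_graph()
    df = pd.read_csv(path)
    if len(df) == 0:
        raise TrialLogError(f"{path}: no trials")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"{path}: missing columns {missing}")
    df["is_pretraining"] = df["is_pretraining"].astype(bool)

    dup = df.duplicated(subset=["subject_id", "session", "trial"])
    if dup.any():
        row = int(df.index[dup][0]) + 2  # header + 1-based
        raise TrialLogError(f"{path}: duplicate (subject, session, trial) at row {row}")

    for idx, t in df.iterrows():
        row = int(idx) + 2
        try:
            succ1 = graph.successors(t.s1, t.a1)
            succ2 = graph.successors(t.s2, t.a2)
        except KeyError as e:
            raise TrialLogError(f"{path}: row {row}: {e}") from e
        if t.s2 not in succ1:
            raise TrialLogError(
                f"{path}: row {row}: s2={t.s2} is not a successor of "
                f"({t.s1},{t.a1})"
            )
        if t.s_outcome not in succ2:
            raise TrialLogError(
                f"{path}: row {row}: s_outcome={t.s_outcome} is not a "
                f"successor of ({t.s2},{t.a2})"
            )

    out = {}
    for subj, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values(
            ["is_pretraining", "session", "trial"],
            ascending=[False, True, True],
        ).reset_index(drop=True)
        if sub.duplicated(subset=["session", "trial"]).any():
            raise TrialLogError(f"{path}: duplicate trial index for {subj}")
        out[str(subj)] = sub
    return out


def write_trial_log(
    logs: Mapping[str, pd.DataFrame] | pd.DataFrame, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(logs, pd.DataFrame):
        df = logs
    else:
        df = pd.concat(logs.values(), ignore_index=True)
    df[LOG_COLUMNS].to_csv(path, index=False)
    return path


def load_task_config(path: str | Path) -> TaskConfig:
    """Load a YAML or JSON task configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return TaskConfig.from_mapping(cfg or {})


def write_fit_result(fit: FitResult, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(fit.to_dict(), indent=2, sort_keys=True))
    return path


def read_fit_result(path: str | Path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def write_outputs(
    results: Mapping, out_dir: str | Path, metadata: Mapping | None = None
) -> list[Path]:
    """Write a mapping of result objects with deterministic file naming.

    DataFrames become ``<name>.csv``, everything JSON-serializable becomes
    ``<name>.json``; a ``run_metadata.json`` captures the config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        elif isinstance(obj, FitResult):
            p = out_dir / f"{name}.json"
            write_fit_result(obj, p)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        written.append(p)
    if metadata is not None:
        p = out_dir / "run_metadata.json"
        p.write_text(json.dumps(dict(metadata), indent=2, sort_keys=True, default=str))
        written.append(p)
    return written
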