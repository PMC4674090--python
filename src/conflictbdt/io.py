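"""Configuration and table serialisation.

Trial tables travel as tidy CSV/TSV with a fixed documented header; run
configuration round-trips losslessly through JSON or YAML, picked by file
extension.  No-go trials carry empty latency and direction fields.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .simulate import TRIAL_COLUMNS, TaskConfig

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "load_config",
    "save_config",
]


class SchemaError(ValueError):
    """A table is missing required columns or has unparseable values."""


_BOOL_COLUMNS = ["went", "token_collected", "caught"]
_FLOAT_COLUMNS = ["approach_latency", "return_latency"]
_INT_COLUMNS = ["subject_id", "epoch_id", "token_index", "threat_level_index", "potential_loss"]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (or TSV for a ``.tsv`` suffix)."""
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    trials[TRIAL_COLUMNS].to_csv(path, sep=sep, index=False)


def _sniff_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table, autodetecting comma/tab delimiters and validating the schema."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    try:
        for c in _INT_COLUMNS:
            df[c] = df[c].astype(np.int64)
        for c in _FLOAT_COLUMNS:
            df[c] = df[c].astype(float)
        for c in _BOOL_COLUMNS:
            df[c] = df[c].map(_to_bool).astype(bool)
        df["correct_direction"] = df["correct_direction"].map(_to_bool).astype("boolean")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path.name}: column parse failure: {exc}") from exc
    return df


def _to_bool(v: Any):
    if pd.isna(v):
        return pd.NA
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "1.0"):
        return True
    if s in ("false", "0", "0.0"):
        return False
    raise ValueError(f"cannot parse boolean value {v!r}")


@dataclass
class RunConfig:
    """Full specification of a demo run: task, agent, analysis and reconstruction options."""

    task: TaskConfig = field(default_factory=TaskConfig)
    agent: dict = field(default_factory=lambda: {"kind": "bdt"})
    n_subjects: int = 10
    seed: int = 0
    log_latency: bool = False
    min_obs: int = 1
    t_max: float = 5.0
    self_consistency_iters: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"]["threat_levels"] = list(d["task"]["threat_levels"])
        for key in ("approach_window", "return_window"):
            d["task"][key] = list(d["task"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        task = d.pop("task", {})
        if task:
            for key in ("threat_levels", "approach_window", "return_window"):
                if key in task:
                    task[key] = tuple(task[key])
        return cls(task=TaskConfig(**task), **d)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialise a run configuration as JSON or YAML, by file extension."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return RunConfig.from_dict(d)
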