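"""Readers/writers for the CSV schemas, config loading, and run manifests.

Timestamps are written with fixed 3-decimal precision so write/read
round-trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulator import (
    EVENT_COLUMNS,
    KNOWN_EVENTS,
    PROFILE_COLUMNS,
    EventLog,
    SimConfig,
)
from .sus import SUSResponse

__all__ = [
    "read_event_log",
    "write_event_log",
    "load_config",
    "read_sus_responses",
    "RunManifest",
    "IOError_",
]


class IOError_(ValueError):
    """Schema violation in an on-disk artifact."""


def write_event_log(log: EventLog, events_path, profiles_path) -> None:
    ev = log.events.copy()
    ev["t_minutes"] = ev["t_minutes"].map(lambda v: f"{v:.3f}")
    ev.to_csv(events_path, index=False)
    pr = log.profiles.copy()
    for col in ("arrival_minutes", "age_months"):
        pr[col] = pr[col].map(lambda v: f"{v:.3f}")
    pr.to_csv(profiles_path, index=False)


def read_event_log(events_path, profiles_path) -> EventLog:
    """Parse, validate and lint an event log; events are re-sorted per patient."""
    events_path, profiles_path = Path(events_path), Path(profiles_path)
    for p in (events_path, profiles_path):
        if not p.exists():
            raise IOError_(f"no such file: {p}")
    ev = pd.read_csv(events_path)
    if list(ev.columns) != EVENT_COLUMNS:
        raise IOError_(
            f"{events_path}: expected columns {EVENT_COLUMNS}, found {list(ev.columns)}"
        )
    bad = ~ev["event"].isin(KNOWN_EVENTS)
    if bad.any():
        line = int(ev.index[bad][0]) + 2  # header is line 1
        raise IOError_(f"{events_path}:{line}: unknown event name {ev.loc[bad, 'event'].iloc[0]!r}")
    if ev["t_minutes"].isna().any():
        line = int(ev.index[ev["t_minutes"].isna()][0]) + 2
        raise IOError_(f"{events_path}:{line}: missing timestamp")
    pr = pd.read_csv(profiles_path)
    if list(pr.columns) != PROFILE_COLUMNS:
        raise IOError_(
            f"{profiles_path}: expected columns {PROFILE_COLUMNS}, found {list(pr.columns)}"
        )
    log = EventLog.from_records(
        ev.values.tolist(), pr.values.tolist()
    )
    try:
        log.lint()
    except ValueError as exc:
        raise IOError_(f"{events_path}: {exc}") from exc
    return log


#: keys a config file may set; anything else is rejected
_CONFIG_KEYS = {
    "seed",
    "n_days",
    "arm",
    "policy",
    "mode",
    "arrivals_per_day",
    "overnight_fraction",
    "overnight_end",
    "resources",
    "lwbs_patience",
    "task_fraction",
    "final_decision_task",
    "start_day",
    "male_fraction",
}


def load_config(path: Optional[str] = None, *, seed: Optional[int] = None, **overrides) -> SimConfig:
    """Load a key-value config file; unknown keys and invariant violations error.

    An empty (or absent) file yields the fully calibrated default
    configuration.  ``seed`` and keyword overrides take precedence over the
    file.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise IOError_(f"{path}: config must be a key-value mapping")
        raw.update(loaded)
    raw.update(overrides)
    if seed is not None:
        raw["seed"] = seed
    raw.setdefault("seed", 0)
    problems = [f"unknown config key {k!r}" for k in raw if k not in _CONFIG_KEYS]
    if "resources" in raw:
        if not isinstance(raw["resources"], dict):
            problems.append("resources must be a mapping role -> count")
        else:
            for role, n in raw["resources"].items():
                if role not in ("nurse", "junior", "senior", "specialist"):
                    problems.append(f"unknown role {role!r}")
                elif not isinstance(n, int) or n < 0:
                    problems.append(f"resource count for {role!r} must be a nonnegative integer")
    if problems:
        raise IOError_("; ".join(problems))
    try:
        return SimConfig(**raw)
    except ValueError as exc:
        raise IOError_(str(exc)) from exc


def read_sus_responses(path) -> list[SUSResponse]:
    """CSV columns: respondent_id, q1..q10, then optional covariates."""
    df = pd.read_csv(path)
    required = ["respondent_id"] + [f"q{i}" for i in range(1, 11)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SUSResponse(
                respondent_id=str(row["respondent_id"]),
                item_scores=tuple(int(row[f"q{i}"]) for i in range(1, 11)),
                age_years=float(row["age_years"]) if "age_years" in df.columns and pd.notna(row.get("age_years")) else None,
                seniority_months=float(row["seniority_months"]) if "seniority_months" in df.columns and pd.notna(row.get("seniority_months")) else None,
                occupation=str(row["occupation"]) if "occupation" in df.columns and pd.notna(row.get("occupation")) else None,
            )
        )
    return out


@dataclasses.dataclass(frozen=True)
class RunManifest:
    """Enough metadata to reproduce a run bit-for-bit."""

    config_hash: str
    seed: int
    tool_version: str
    created_unix: float
    outputs: tuple

    @classmethod
    def create(cls, config: SimConfig, outputs: list[str]) -> "RunManifest":
        from . import __version__

        payload = {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if isinstance(v, (int, float, str, bool, dict, type(None)))
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return cls(
            config_hash=digest,
            seed=config.seed,
            tool_version=__version__,
            created_unix=time.time(),
            outputs=tuple(outputs),
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
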