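"""CSV dialects for time trials and session logs.

All quantities are SI: distances m, times s, speeds m/s — no unit
autodetection is attempted.
"""

from __future__ import annotations

from os import PathLike

import pandas as pd

from .cs_model import TimeTrial

TRIAL_COLUMNS = ["swimmer_id", "distance_m", "time_s"]
SESSION_COLUMNS = [
    "swimmer_id",
    "lap_index",
    "lap_distance_m",
    "lap_time_s",
    "rest_after_s",
    "exhausted",
]


class MalformedTableError(ValueError):
    """A CSV is missing required columns or contains unusable rows."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedTableError(f"{what} is missing columns {missing}")


def read_time_trials(path: str | PathLike) -> pd.DataFrame:
    """Read a time-trial table (swimmer_id, distance_m, time_s)."""
    df = pd.read_csv(path)
    if df.empty:
        raise MalformedTableError(f"{path}: empty time-trial file")
    _require_columns(df, TRIAL_COLUMNS, "time-trial CSV")
    bad = df[(df.distance_m <= 0) | (df.time_s <= 0)]
    if not bad.empty:
        lines = (bad.index + 2).tolist()  # +2: header and 0-base
        raise MalformedTableError(
            f"{path}: non-positive distance/time on line(s) {lines}"
        )
    return df


def write_time_trials(df: pd.DataFrame, path: str | PathLike) -> None:
    _require_columns(df, TRIAL_COLUMNS, "time-trial frame")
    df.to_csv(path, index=False)


def trials_for_swimmer(df: pd.DataFrame, swimmer_id: str) -> list[TimeTrial]:
    sub = df[df.swimmer_id == swimmer_id]
    return [TimeTrial(r.distance_m, r.time_s) for r in sub.itertuples()]


def read_session_log(path: str | PathLike) -> pd.DataFrame:
    """Read a per-lap session log; see SESSION_COLUMNS for the dialect."""
    df = pd.read_csv(path)
    if df.empty:
        raise MalformedTableError(f"{path}: empty session log")
    _require_columns(df, SESSION_COLUMNS, "session-log CSV")
    return df


def write_session_log(df: pd.DataFrame, path: str | PathLike) -> None:
    _require_columns(df, SESSION_COLUMNS, "session-log frame")
    df.to_csv(path, index=False)
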