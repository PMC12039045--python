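"""CSV round-tripping for patients, events and aggregated series.

Months are encoded as ISO "YYYY-MM" on disk and as integer indices (window
start = 0, burn-in months negative) in memory; an open registration end is
an empty field. Flag columns are written 0/1 under their label names.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calendar import StudyCalendar

__all__ = [
    "write_patients",
    "read_patients",
    "write_events",
    "read_events",
    "write_series",
    "read_series",
]

_CORE_PATIENT_COLS = ("patient_id", "reg_start", "reg_end")


def _iso(calendar: StudyCalendar, t: pd.Series) -> pd.Series:
    return t.map(lambda v: calendar.month_of(int(v)))


def write_patients(patients: pd.DataFrame, path: str | Path, calendar: StudyCalendar) -> None:
    out = patients.copy()
    out["reg_start"] = _iso(calendar, out["reg_start"])
    out["reg_end"] = out["reg_end"].map(
        lambda v: "" if np.isinf(v) else calendar.month_of(int(v))
    )
    out.to_csv(path, index=False)


def read_patients(path: str | Path, calendar: StudyCalendar) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"reg_end": "string"})
    df["reg_start"] = df["reg_start"].map(calendar.t_index)
    df["reg_end"] = df["reg_end"].map(
        lambda v: np.inf if pd.isna(v) or v == "" else float(calendar.t_index(v))
    )
    for col in df.columns:
        if col not in _CORE_PATIENT_COLS:
            df[col] = df[col].astype(np.int8)
    return df


def write_events(events: pd.DataFrame, path: str | Path, calendar: StudyCalendar) -> None:
    out = events.copy()
    out["month"] = _iso(calendar, out["month"])
    out.to_csv(path, index=False)


def read_events(path: str | Path, calendar: StudyCalendar) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["month"] = df["month"].map(calendar.t_index)
    return df


def write_series(series: pd.DataFrame, path: str | Path, calendar: StudyCalendar) -> None:
    out = series.copy()
    out.insert(0, "month_iso", _iso(calendar, out["month"]))
    out.to_csv(path, index=False)


def read_series(path: str | Path, calendar: StudyCalendar) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "month" not in df.columns and "month_iso" in df.columns:
        df["month"] = df["month_iso"].map(calendar.t_index)
    df = df.drop(columns=[c for c in ("month_iso",) if c in df.columns])
    return df
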