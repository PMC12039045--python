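"""Monthly numerators and denominators from event-level records.

Two outcomes are counted per month and subgroup:

* prevalent prescribing — distinct registered patients with at least one
  prescription issue in the month (multiple issues count once);
* new prescribing — such patients with no issue in the 24 calendar months
  strictly before the index month, counted against the antidepressant-naive
  registered denominator.

Statistical disclosure control (redact counts of five or fewer, round the
rest to the nearest ten) is a separate, pure transformation applied only to
published outputs — never to the series handed to the model.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from .calendar import StudyCalendar

__all__ = [
    "DataIntegrityError",
    "InsufficientHistoryError",
    "UndefinedRateError",
    "monthly_prevalent_counts",
    "monthly_new_counts",
    "apply_disclosure_control",
    "rate_per_1000",
    "assign_drug_class",
    "WASHOUT_MONTHS",
]

WASHOUT_MONTHS = 24


class DataIntegrityError(ValueError):
    """Events reference unknown patients or unknown drug classes."""


class InsufficientHistoryError(ValueError):
    """Not enough pre-window history to decide the washout rule."""


class UndefinedRateError(ZeroDivisionError):
    """Rate requested with a zero denominator."""


def _check_ids(events: pd.DataFrame, patients: pd.DataFrame) -> None:
    unknown = set(events["patient_id"]) - set(patients["patient_id"])
    if unknown:
        shown = sorted(unknown)[:10]
        raise DataIntegrityError(
            f"{len(unknown)} event patient id(s) not in the registration "
            f"records, e.g. {shown}"
        )


def _subgroup_mask(patients: pd.DataFrame, subgroup: str) -> np.ndarray:
    if subgroup == "all":
        return np.ones(len(patients), dtype=bool)
    if subgroup not in patients.columns:
        raise DataIntegrityError(f"unknown subgroup flag {subgroup!r}")
    return patients[subgroup].to_numpy(dtype=bool)


def _registered_counts(
    patients: pd.DataFrame, ts: np.ndarray
) -> np.ndarray:
    """Registered patients at each month index in ``ts`` (vectorised)."""
    starts = np.sort(patients["reg_start"].to_numpy())
    ends = np.sort(patients["reg_end"].to_numpy(dtype=float))
    started = np.searchsorted(starts, ts, side="right")
    ended = np.searchsorted(ends, ts, side="right")
    return started - ended


def monthly_prevalent_counts(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    calendar: StudyCalendar,
    subgroup: str = "all",
) -> pd.DataFrame:
    """Prevalent prescribing series for one subgroup.

    Returns a frame with ``month`` (0..T-1), ``subgroup``, ``outcome``
    (= "prevalent"), ``numerator``, ``denominator``, ``redacted`` (False).
    """
    _check_ids(events, patients)
    pats = patients.loc[_subgroup_mask(patients, subgroup)]
    ts = np.arange(calendar.n_months)
    den = _registered_counts(pats, ts)

    ev = events.merge(
        pats[["patient_id", "reg_start", "reg_end"]], on="patient_id", how="inner"
    )
    ev = ev[(ev["month"] >= 0) & (ev["month"] < calendar.n_months)]
    ev = ev[(ev["reg_start"] <= ev["month"]) & (ev["month"] < ev["reg_end"])]
    counts = (
        ev.drop_duplicates(["patient_id", "month"])
        .groupby("month")
        .size()
        .reindex(ts, fill_value=0)
    )
    return pd.DataFrame(
        {
            "month": ts,
            "subgroup": subgroup,
            "outcome": "prevalent",
            "numerator": counts.to_numpy(),
            "denominator": den,
            "redacted": False,
        }
    )


def monthly_new_counts(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    calendar: StudyCalendar,
    subgroup: str = "all",
    washout: int = WASHOUT_MONTHS,
    naive_denominator: bool = True,
) -> pd.DataFrame:
    """New (incident) prescribing series for one subgroup.

    A patient counts as new in month t when they have an issue at t and none
    in months [t-washout, t-1]. The denominator is the antidepressant-naive
    registered population (same washout rule, issue at t allowed); pass
    ``naive_denominator=False`` for the all-registered alternative.

    Raises :class:`InsufficientHistoryError` when registration records do
    not reach back ``washout`` months before the window — the washout would
    otherwise be silently undecidable at month 0.
    """
    _check_ids(events, patients)
    if patients["reg_start"].min() > -washout:
        raise InsufficientHistoryError(
            f"need event history from month {-washout}; earliest registration "
            f"starts at {int(patients['reg_start'].min())}"
        )
    pats = patients.loc[_subgroup_mask(patients, subgroup)].reset_index(drop=True)
    T = calendar.n_months
    ts = np.arange(T)
    n = len(pats)

    # boolean event matrix over months -washout .. T-1 for this subgroup
    first_col = -washout
    n_cols = T + washout
    pid_to_row = pd.Series(np.arange(n), index=pats["patient_id"].to_numpy())
    ev = events[
        (events["month"] >= first_col)
        & (events["month"] < T)
        & events["patient_id"].isin(pid_to_row.index)
    ]
    E = np.zeros((n, n_cols), dtype=np.int32)
    rows = pid_to_row[ev["patient_id"].to_numpy()].to_numpy()
    cols = ev["month"].to_numpy() - first_col
    E[rows, cols] = 1

    cum = np.cumsum(E, axis=1)
    reg_start = pats["reg_start"].to_numpy()
    reg_end = pats["reg_end"].to_numpy(dtype=float)

    num = np.zeros(T, dtype=int)
    den = np.zeros(T, dtype=int)
    for t in ts:
        hi = cum[:, t + washout - 1]  # events through month t-1
        lo = cum[:, t - 1] if t >= 1 else 0  # events through month t-washout-1
        recent = (hi - lo) > 0
        registered = (reg_start <= t) & (t < reg_end)
        naive = registered & ~recent
        num[t] = int(np.sum(naive & (E[:, t + washout] > 0)))
        den[t] = int(np.sum(naive)) if naive_denominator else int(np.sum(registered))
    return pd.DataFrame(
        {
            "month": ts,
            "subgroup": subgroup,
            "outcome": "new",
            "numerator": num,
            "denominator": den,
            "redacted": False,
        }
    )


# ---------------------------------------------------------------------------
# disclosure control and descriptive arithmetic
# ---------------------------------------------------------------------------

def _round_to_ten(values: np.ndarray, ties: str) -> np.ndarray:
    v = values.astype(float)
    if ties == "away-from-zero":
        return np.sign(v) * np.floor(np.abs(v) / 10.0 + 0.5) * 10.0
    if ties == "to-even":
        return np.round(v / 10.0) * 10.0
    raise ValueError(f"unknown tie rule {ties!r}")


def disclosure_round(count: int, ties: str = "away-from-zero") -> int | None:
    """Single-count disclosure control: None (redacted) or a multiple of 10."""
    if count <= 5:
        return None
    return int(_round_to_ten(np.asarray([count]), ties)[0])


def apply_disclosure_control(
    series: pd.DataFrame,
    redact_threshold: int = 5,
    redact_zero: bool = True,
    ties: str = "away-from-zero",
) -> pd.DataFrame:
    """Redact small counts and round the rest to the nearest ten.

    Counts of ``redact_threshold`` or fewer are removed and the row flagged
    ``redacted``; remaining counts are rounded to the nearest 10 (ties away
    from zero by default). Pure: the input frame is untouched; applying the
    control twice changes nothing (multiples of ten are fixed points).
    ``redact_zero=False`` leaves exact zeros visible (redacting 1-5 only).
    """
    out = series.copy()
    num = out["numerator"].to_numpy(dtype=float)
    den = out["denominator"].to_numpy(dtype=float)
    redact = num <= redact_threshold
    if not redact_zero:
        redact &= num > 0
    redact |= np.isnan(num)  # keeps already-redacted rows redacted
    num_r = _round_to_ten(num, ties)
    den_r = np.where(den <= redact_threshold, np.nan, _round_to_ten(den, ties))
    out["numerator"] = pd.array(
        np.where(redact, np.nan, num_r), dtype="Int64"
    )
    out["denominator"] = pd.array(den_r, dtype="Int64")
    out["redacted"] = redact | np.isnan(den_r)
    return out


def rate_per_1000(numerator: float, denominator: float) -> float:
    """Prescribing rate per 1000 patients, reported to one decimal."""
    if denominator == 0:
        raise UndefinedRateError("rate undefined: zero denominator")
    return float(np.round(1000.0 * numerator / denominator, 1))


def assign_drug_class(classes: Iterable[str]) -> str:
    """Collapse a patient-month's prescription classes to one label.

    MAOIs merge into "other"; a single remaining class names itself; two or
    more distinct classes in the month become "multiple".
    """
    mapped = set()
    for c in classes:
        if c not in {"ssri", "tricyclic", "maoi", "other"}:
            raise DataIntegrityError(f"unknown drug class {c!r}")
        mapped.add("other" if c == "maoi" else c)
    if not mapped:
        raise DataIntegrityError("no prescriptions in the month")
    return mapped.pop() if len(mapped) == 1 else "multiple"
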