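"""Study calendar: month indexing, interruption points and outlier months.

The analysis window is a contiguous run of calendar months mapped to integer
indices (window start = 0; months before the window carry negative indices).
Two interruption points split the window into pre-interruption, restrictions
and recovery segments, and a small set of months may be flagged as extreme
outliers to be absorbed by dummy variables in the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import pandas as pd

__all__ = ["CalendarError", "StudyCalendar"]


class CalendarError(ValueError):
    """Raised when a study calendar is internally inconsistent."""


def _period(month: str | pd.Period) -> pd.Period:
    try:
        return pd.Period(month, freq="M")
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise CalendarError(f"not a parseable ISO month: {month!r}") from exc


@dataclass(frozen=True)
class StudyCalendar:
    """Maps ISO months ("YYYY-MM") to model time indices.

    Parameters
    ----------
    start_month, end_month:
        Inclusive bounds of the analysis window.
    restrictions_start:
        First month of the first interruption segment (index ``interruption_1``).
    recovery_start:
        First month of the second interruption segment (index ``interruption_2``).
    outlier_months:
        Months modelled with their own dummy variable; must lie inside the
        restrictions segment ``[interruption_1, interruption_2)``.
    """

    start_month: str
    end_month: str
    restrictions_start: str
    recovery_start: str
    outlier_months: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outlier_months", tuple(self.outlier_months))
        last = self.t_index(self.end_month)
        i1, i2 = self.interruption_1, self.interruption_2
        if last < 1:
            raise CalendarError("window must span at least two months")
        if not (0 < i1 < i2 <= last):
            raise CalendarError(
                f"interruptions must satisfy 0 < {i1} < {i2} <= {last}"
            )
        for m in self.outlier_months:
            t = self.t_index(m)
            if not (i1 <= t < i2):
                raise CalendarError(
                    f"outlier month {m} outside the restrictions segment"
                )

    @cached_property
    def _origin(self) -> pd.Period:
        return _period(self.start_month)

    def t_index(self, month: str | pd.Period) -> int:
        """Integer index of ``month`` relative to the window start."""
        return (_period(month) - self._origin).n

    def month_of(self, t: int) -> str:
        """ISO month at index ``t`` (negative indices precede the window)."""
        return str(self._origin + int(t))

    @cached_property
    def n_months(self) -> int:
        return self.t_index(self.end_month) + 1

    @cached_property
    def interruption_1(self) -> int:
        return self.t_index(self.restrictions_start)

    @cached_property
    def interruption_2(self) -> int:
        return self.t_index(self.recovery_start)

    @cached_property
    def outlier_indices(self) -> tuple[int, ...]:
        return tuple(self.t_index(m) for m in self.outlier_months)

    def months(self) -> list[str]:
        """All ISO months in the window, in order."""
        return [self.month_of(t) for t in range(self.n_months)]

    @classmethod
    def covid_study(cls) -> "StudyCalendar":
        """The 60-month pandemic study design: a Jan 2018 - Dec 2022 window
        with interruptions in March 2020 (restrictions) and March 2021
        (recovery) and March/April 2020 flagged as outliers."""
        return cls(
            start_month="2018-01",
            end_month="2022-12",
            restrictions_start="2020-03",
            recovery_start="2021-03",
            outlier_months=("2020-03", "2020-04"),
        )

    def to_dict(self) -> dict:
        return {
            "start_month": self.start_month,
            "end_month": self.end_month,
            "restrictions_start": self.restrictions_start,
            "recovery_start": self.recovery_start,
            "outlier_months": list(self.outlier_months),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyCalendar":
        return cls(
            start_month=d["start_month"],
            end_month=d["end_month"],
            restrictions_start=d["restrictions_start"],
            recovery_start=d["recovery_start"],
            outlier_months=tuple(d.get("outlier_months", ())),
        )
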