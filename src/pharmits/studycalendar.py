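"""Study calendar: the 60-month window January 2018 – December 2022.

Months are addressed by a 1-based ``month_index`` (January 2018 = 1,
December 2022 = 60).  The pre-pandemic period spans indices 1–26
(January 2018 – February 2020) and the pandemic period indices 27–60
(March 2020 – December 2022).
"""

from __future__ import annotations

import calendar as _pycal
from dataclasses import dataclass

from .errors import OutOfWindowError

START_YEAR, START_MONTH = 2018, 1
END_YEAR, END_MONTH = 2022, 12
N_MONTHS = 60

#: Month indices before the pandemic onset (Jan 2018 – Feb 2020).
PRE_COVID_RANGE = range(1, 27)
#: Month indices of the pandemic period (Mar 2020 – Dec 2022).
COVID_RANGE = range(27, 61)

MARCH_2020 = 27
JUNE_2020 = 30
DECEMBER_2021 = 48
DECEMBER_2022 = 60

_MONTH_NAMES = _pycal.month_name


def month_index(year: int, month: int) -> int:
    """Map a calendar month to its 1-based index in the study window.

    Raises :class:`OutOfWindowError` for dates outside
    January 2018 – December 2022.
    """
    if not 1 <= month <= 12:
        raise OutOfWindowError(f"invalid calendar month {month}")
    idx = (year - START_YEAR) * 12 + month
    if not 1 <= idx <= N_MONTHS:
        raise OutOfWindowError(
            f"{_MONTH_NAMES[month]} {year} is outside the study window "
            f"(January {START_YEAR} – December {END_YEAR})"
        )
    return idx


def year_month(index: int) -> tuple[int, int]:
    """Inverse of :func:`month_index`: index -> (year, month)."""
    _check_index(index)
    return START_YEAR + (index - 1) // 12, (index - 1) % 12 + 1


def quarter_of(index: int) -> tuple[int, int]:
    """Calendar quarter label (year, 1–4) of a month index."""
    year, month = year_month(index)
    return year, (month - 1) // 3 + 1


def days_in_month(index: int) -> int:
    """Number of days of the calendar month at ``index`` (handles leap years)."""
    year, month = year_month(index)
    return _pycal.monthrange(year, month)[1]


def month_label(index: int) -> str:
    """Human-readable label, e.g. ``'June 2020'``."""
    year, month = year_month(index)
    return f"{_MONTH_NAMES[month]} {year}"


def months_of_quarter(year: int, quarter: int) -> list[int]:
    """The three month indices of quarter ``quarter`` (1–4) in ``year``."""
    if not 1 <= quarter <= 4:
        raise OutOfWindowError(f"invalid quarter {quarter}")
    first = (quarter - 1) * 3 + 1
    return [month_index(year, first + k) for k in range(3)]


def _check_index(index: int) -> None:
    if not 1 <= int(index) <= N_MONTHS:
        raise OutOfWindowError(f"month index {index} outside 1..{N_MONTHS}")


@dataclass(frozen=True)
class StudyCalendar:
    """The fixed 60-month study calendar as an object.

    Thin wrapper over the module-level functions so downstream code can
    take a calendar argument; all instances are identical.
    """

    start: tuple[int, int] = (START_YEAR, START_MONTH)
    end: tuple[int, int] = (END_YEAR, END_MONTH)
    n_months: int = N_MONTHS

    @property
    def pre_covid_range(self) -> range:
        return PRE_COVID_RANGE

    @property
    def covid_range(self) -> range:
        return COVID_RANGE

    def month_index(self, year: int, month: int) -> int:
        return month_index(year, month)

    def year_month(self, index: int) -> tuple[int, int]:
        return year_month(index)

    def quarter_of(self, index: int) -> tuple[int, int]:
        return quarter_of(index)

    def days_in_month(self, index: int) -> int:
        return days_in_month(index)


#: Shared default calendar instance.
STUDY_CALENDAR = StudyCalendar()
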