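"""Drug-utilization outcomes: DDD/TID, treatment incidence and relative change.

Dispensed volume of a period p (month or quarter) is expressed as DDD per
thousand inhabitants per day::

    v_p = (sum_m u_{m,p}) / (d_p * n_p) * 1000

with u the dispensed DDD per month, d_p the total days in the period and
n_p the period's population size.  Treatment incidence is incident
recipients per 100,000 persons::

    incidence_p = (sum k_p) / (sum n_p) * 100000

Relative quarterly change uses 2019 as the pre-pandemic base year::

    delta_{q,y} = (value_{q,y} / value_{q,2019} - 1) * 100

An incident recipient in month m is a person with at least one
antidepressant (ATC N06A) dispensing in m and none in the 12 calendar
months m-12 .. m-1 (month-level washout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd

from . import studycalendar as cal
from .errors import (
    InsufficientHistoryError,
    MissingDataError,
    OutOfWindowError,
    UndefinedMetricError,
)
from .io import MonthlySeries

#: A period is a single study month index (1..60) or a (year, quarter) pair.
Period = Union[int, tuple[int, int]]


@dataclass(frozen=True)
class PeriodVolume:
    """Dispensed volume of one period in DDD/TID."""

    period: Period
    v: float
    numerator_ddd: float
    person_days: float


@dataclass(frozen=True)
class PeriodIncidence:
    """Incident recipients per 100,000 persons in one period."""

    period: Period
    incidence: float
    incident_count: float
    population: float


@dataclass(frozen=True)
class RelativeChange:
    """Percent change of a quarter versus the same quarter of 2019."""

    quarter: int
    year: int
    delta_pct: float


def _period_months(period: Period) -> list[int]:
    if isinstance(period, tuple):
        year, quarter = period
        return cal.months_of_quarter(year, quarter)
    cal._check_index(period)
    return [int(period)]


def compute_dddtid(series: MonthlySeries, period: Period) -> PeriodVolume:
    """DDD/TID of ``period`` (a month index or (year, quarter) pair).

    For multi-month periods the population n_p is the mean of the monthly
    populations and d_p the exact sum of days, which reduces to the
    single-period formula when population is constant.
    """
    months = _period_months(period)
    sub = series.data.loc[months]
    u = float(sub["ddd"].sum())
    d_p = float(sub["days"].sum())
    n_p = float(sub["population"].mean())
    if n_p <= 0:
        raise UndefinedMetricError(f"period {period}: population is zero")
    person_days = d_p * n_p
    return PeriodVolume(period=period, v=u / person_days * 1000.0, numerator_ddd=u, person_days=person_days)


def compute_incidence(series: MonthlySeries, period: Period) -> PeriodIncidence:
    """Incidence per 100,000 of ``period``; requires incident counts present."""
    months = _period_months(period)
    sub = series.data.loc[months]
    if sub["incident_count"].isna().any():
        gaps = [cal.month_label(i) for i in sub.index[sub["incident_count"].isna()]]
        raise MissingDataError(
            f"region '{series.region}', stratum {series.age_group}/{series.sex}: "
            f"incident counts absent for {', '.join(gaps)}"
        )
    k = float(sub["incident_count"].sum())
    n = float(sub["population"].sum())
    if n <= 0:
        raise UndefinedMetricError(f"period {period}: population is zero")
    return PeriodIncidence(period=period, incidence=k / n * 100000.0, incident_count=k, population=n)


def monthly_dddtid(series: MonthlySeries) -> pd.Series:
    """DDD/TID for each of the 60 study months (the ITS outcome vector)."""
    d = series.data
    v = d["ddd"].to_numpy() / (d["days"].to_numpy() * d["population"].to_numpy()) * 1000.0
    return pd.Series(v, index=d.index, name="dddtid")


def monthly_incidence(series: MonthlySeries) -> pd.Series:
    """Incidence per 100,000 for each study month (the ITS outcome vector)."""
    d = series.data
    if d["incident_count"].isna().any():
        raise MissingDataError(
            f"region '{series.region}', stratum {series.age_group}/{series.sex}: "
            "incident counts absent"
        )
    v = d["incident_count"].to_numpy() / d["population"].to_numpy() * 100000.0
    return pd.Series(v, index=d.index, name="incidence")


def relative_change(
    metric_by_quarter: Mapping[tuple[int, int], Union[float, PeriodVolume, PeriodIncidence]],
    quarter: int,
    year: int,
) -> RelativeChange:
    """Percent change of (quarter, year) versus (quarter, 2019).

    ``metric_by_quarter`` maps (year, quarter) to a metric value or a
    :class:`PeriodVolume`/:class:`PeriodIncidence`.
    """

    def _value(x):
        if isinstance(x, PeriodVolume):
            return x.v
        if isinstance(x, PeriodIncidence):
            return x.incidence
        return float(x)

    base = _value(metric_by_quarter[(2019, quarter)])
    if base == 0:
        raise UndefinedMetricError(f"quarter {quarter} 2019 base value is zero")
    val = _value(metric_by_quarter[(year, quarter)])
    return RelativeChange(quarter=quarter, year=year, delta_pct=(val / base - 1.0) * 100.0)


# -- incident counts from person-level events -------------------------

_STRATUM_COLS = ["region", "age_group", "sex"]


def derive_incident_counts(
    events: pd.DataFrame,
    months: Iterable[int] | None = None,
    history_start: tuple[int, int] | None = None,
    atc_prefix: str = "N06A",
) -> pd.DataFrame:
    """Monthly incident-recipient counts from person-level dispensings.

    A person is incident in study month m iff they have at least one
    dispensing with ATC code starting with ``atc_prefix`` in m and none
    in the 12 calendar months before m; multiple dispensings within the
    incident month count once.

    Parameters
    ----------
    events
        DataFrame with columns ``person_id``, ``dispensing_date``
        (parseable to dates), ``atc_code`` and optionally the stratum
        columns ``region``, ``age_group``, ``sex``.
    months
        Study month indices for which counts are requested
        (default: all 60).  Each requested month must have a full
        12-month lookback available in the data.
    history_start
        (year, month) of the first month with complete event coverage;
        defaults to the earliest event month.

    Returns
    -------
    DataFrame with columns region, age_group, sex, month_index,
    incident_count ("all" fills absent stratum columns), zero-filled
    over the requested months.
    """
    months = sorted(range(1, cal.N_MONTHS + 1) if months is None else {int(m) for m in months})
    for m in months:
        cal._check_index(m)

    ev = events.copy()
    dates = pd.to_datetime(ev["dispensing_date"])
    ev["_abs_month"] = dates.dt.year * 12 + dates.dt.month
    end_abs = cal.END_YEAR * 12 + cal.END_MONTH
    if (ev["_abs_month"] > end_abs).any():
        raise OutOfWindowError("events contain dispensings after the study window")
    ev = ev[ev["atc_code"].astype(str).str.startswith(atc_prefix)]

    if history_start is None:
        first = int(ev["_abs_month"].min()) if len(ev) else end_abs
        hist_abs = first
    else:
        hist_abs = history_start[0] * 12 + history_start[1]

    base_abs = cal.START_YEAR * 12 + cal.START_MONTH  # abs month of index 1
    for m in months:
        if (base_abs + m - 1) - 12 < hist_abs:
            raise InsufficientHistoryError(
                f"{cal.month_label(m)} lacks a full 12-month lookback "
                f"(history starts at absolute month {hist_abs})"
            )

    stratum_cols = [c for c in _STRATUM_COLS if c in ev.columns]
    groups = ev.groupby(stratum_cols, sort=True) if stratum_cols else [((), ev)]

    requested = set(months)
    rows = []
    for key, grp in groups:
        if stratum_cols and not isinstance(key, tuple):
            key = (key,)
        counts = dict.fromkeys(months, 0)
        for _, person in grp.groupby("person_id", sort=False):
            pm = np.unique(person["_abs_month"].to_numpy())
            prev = np.concatenate(([-np.inf], pm[:-1]))
            incident = pm[(pm - prev) > 12]
            for am in incident:
                sm = int(am) - base_abs + 1
                if sm in requested:
                    counts[sm] += 1
        labels = dict(zip(stratum_cols, key))
        for m in months:
            rows.append(
                {
                    "region": labels.get("region", "all"),
                    "age_group": labels.get("age_group", "all"),
                    "sex": labels.get("sex", "all"),
                    "month_index": m,
                    "incident_count": counts[m],
                }
            )
    return pd.DataFrame(rows, columns=_STRATUM_COLS + ["month_index", "incident_count"])


# -- tabular exports ---------------------------------------------------


def quarterly_metric_table(
    series: dict[tuple[str, str, str], MonthlySeries] | list[MonthlySeries],
    metric: str = "dddtid",
) -> pd.DataFrame:
    """Quarterly metric values for all series.

    ``metric`` is ``"dddtid"`` or ``"incidence"``.  Columns: region,
    age_group, sex, year, quarter, metric, value.
    """
    items = list(series.values()) if isinstance(series, dict) else list(series)
    rows = []
    for s in items:
        for year in range(cal.START_YEAR, cal.END_YEAR + 1):
            for q in range(1, 5):
                if metric == "dddtid":
                    value = compute_dddtid(s, (year, q)).v
                elif metric == "incidence":
                    value = compute_incidence(s, (year, q)).incidence
                else:
                    raise ValueError(f"unknown metric {metric!r}")
                rows.append(
                    {
                        "region": s.region,
                        "age_group": s.age_group,
                        "sex": s.sex,
                        "year": year,
                        "quarter": q,
                        "metric": metric,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


def relative_change_table(quarterly: pd.DataFrame) -> pd.DataFrame:
    """Relative change versus 2019 for each row of a quarterly metric table."""
    out = []
    for (region, age, sex, metric), grp in quarterly.groupby(
        ["region", "age_group", "sex", "metric"]
    ):
        lookup = {(int(r.year), int(r.quarter)): r.value for r in grp.itertuples()}
        for r in grp.itertuples():
            rc = relative_change(lookup, int(r.quarter), int(r.year))
            out.append(
                {
                    "region": region,
                    "age_group": age,
                    "sex": sex,
                    "metric": metric,
                    "year": int(r.year),
                    "quarter": int(r.quarter),
                    "delta_pct": rc.delta_pct,
                }
            )
    return pd.DataFrame(out)
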