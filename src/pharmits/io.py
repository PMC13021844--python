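"""Canonical long-format dispensing tables and validated readers/writers.

The on-disk format is a UTF-8 CSV with header
``region,age_group,sex,year,month,ddd,population,days,incident_count``
("." decimal separator).  One row per region, stratum and calendar month;
``incident_count`` may be empty where incident data are not available.
Every (region, age_group, sex) group must cover all 60 study months with
no gaps or duplicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import studycalendar as cal
from .errors import GapError, ValidationError

#: Closed stratum vocabularies.  "all" denotes the unstratified series.
AGE_GROUPS = ("0-17", "18-44", "45-64", "65-74", "75+", "all")
SEXES = ("female", "male", "all")

CSV_COLUMNS = [
    "region",
    "age_group",
    "sex",
    "year",
    "month",
    "ddd",
    "population",
    "days",
    "incident_count",
]


@dataclass
class MonthlySeries:
    """One region/stratum's aligned 60-month dispensing series.

    ``data`` is indexed by study month index 1..60 with columns
    ``ddd`` (dispensed DDD total, float), ``population`` (int),
    ``days`` (days in month, int) and ``incident_count`` (float, NaN
    where incident data are absent).
    """

    region: str
    age_group: str
    sex: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        region: str,
        age_group: str,
        sex: str,
        ddd: np.ndarray,
        population: np.ndarray,
        days: np.ndarray | None = None,
        incident_count: np.ndarray | None = None,
    ) -> "MonthlySeries":
        """Build a series from 60-long arrays; ``days`` defaults to the calendar."""
        idx = pd.RangeIndex(1, cal.N_MONTHS + 1, name="month_index")
        if days is None:
            days = np.array([cal.days_in_month(i) for i in idx])
        if incident_count is None:
            incident_count = np.full(cal.N_MONTHS, np.nan)
        data = pd.DataFrame(
            {
                "ddd": np.asarray(ddd, dtype=float),
                "population": np.asarray(population, dtype=np.int64),
                "days": np.asarray(days, dtype=np.int64),
                "incident_count": np.asarray(incident_count, dtype=float),
            },
            index=idx,
        )
        return cls(region=region, age_group=age_group, sex=sex, data=data)

    # -- validation ---------------------------------------------------

    @property
    def stratum(self) -> tuple[str, str]:
        return (self.age_group, self.sex)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.region, self.age_group, self.sex)

    @property
    def has_incidence(self) -> bool:
        return bool(self.data["incident_count"].notna().all())

    def validate(self) -> None:
        name = f"region '{self.region}', stratum {self.age_group}/{self.sex}"
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"{name}: unknown age group label")
        if self.sex not in SEXES:
            raise ValidationError(f"{name}: unknown sex label")
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(
                f"{name}: duplicate months {[cal.month_label(i) for i in dups]}"
            )
        missing = sorted(set(range(1, cal.N_MONTHS + 1)) - set(idx))
        if missing:
            raise GapError(
                f"{name}: missing {', '.join(cal.month_label(i) for i in missing)}"
            )
        extra = sorted(set(idx) - set(range(1, cal.N_MONTHS + 1)))
        if extra:
            raise ValidationError(f"{name}: month indices outside 1..60: {extra}")
        self.data = self.data.sort_index()
        if (self.data["population"] <= 0).any():
            raise ValidationError(f"{name}: population must be positive every month")
        if (self.data["ddd"] < 0).any():
            raise ValidationError(f"{name}: dispensed DDD must be non-negative")
        days = self.data["days"]
        if ((days < 28) | (days > 31)).any():
            raise ValidationError(f"{name}: days per month must lie in 28..31")
        # days are data (e.g. registry conventions); only warn on mismatch
        expected = np.array([cal.days_in_month(i) for i in self.data.index])
        off = self.data.index[days.to_numpy() != expected]
        if len(off):
            warnings.warn(
                f"{name}: stored days differ from calendar at "
                f"{[cal.month_label(i) for i in off]}",
                stacklevel=2,
            )
        counts = self.data["incident_count"]
        if (counts.dropna() < 0).any():
            raise ValidationError(f"{name}: incident counts must be non-negative")

    # -- serialization ------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format rows of this series in the canonical CSV schema."""
        years, months = zip(*(cal.year_month(i) for i in self.data.index))
        out = pd.DataFrame(
            {
                "region": self.region,
                "age_group": self.age_group,
                "sex": self.sex,
                "year": years,
                "month": months,
                "ddd": self.data["ddd"].to_numpy(),
                "population": self.data["population"].to_numpy(),
                "days": self.data["days"].to_numpy(),
                "incident_count": self.data["incident_count"].to_numpy(),
            }
        )
        return out


def read_monthly_series(path) -> dict[tuple[str, str, str], MonthlySeries]:
    """Read a canonical long-format CSV into validated monthly series.

    Returns a dict keyed by (region, age_group, sex).  Raises
    :class:`GapError` naming the first missing month of any group and
    :class:`ValidationError` for schema or value violations.
    """
    table = pd.read_csv(path, dtype={"region": str, "age_group": str, "sex": str})
    missing_cols = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"missing columns: {missing_cols}")
    return series_from_table(table)


def series_from_table(table: pd.DataFrame) -> dict[tuple[str, str, str], MonthlySeries]:
    """Group a long-format DataFrame into validated :class:`MonthlySeries`."""
    out: dict[tuple[str, str, str], MonthlySeries] = {}
    for (region, age_group, sex), grp in table.groupby(
        ["region", "age_group", "sex"], sort=True
    ):
        idx = pd.Index(
            [cal.month_index(int(y), int(m)) for y, m in zip(grp["year"], grp["month"])],
            name="month_index",
        )
        data = pd.DataFrame(
            {
                "ddd": grp["ddd"].to_numpy(dtype=float),
                "population": grp["population"].to_numpy(dtype=np.int64),
                "days": grp["days"].to_numpy(dtype=np.int64),
                "incident_count": grp["incident_count"].to_numpy(dtype=float),
            },
            index=idx,
        )
        series = MonthlySeries(region=str(region), age_group=str(age_group), sex=str(sex), data=data)
        out[series.key] = series
    return out


def write_monthly_series(
    series: dict[tuple[str, str, str], MonthlySeries] | list[MonthlySeries], path
) -> None:
    """Write series to the canonical long-format CSV (round-trip safe)."""
    items = list(series.values()) if isinstance(series, dict) else list(series)
    frames = [s.to_frame() for s in items]
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False)
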