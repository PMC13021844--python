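"""Loader shim for externally deposited dispensing tables.

Public depositions of registry extracts vary in column naming; this
entry point maps a deposit's columns onto the canonical schema and
routes the result through the same validation as
:func:`pharmits.io.read_monthly_series`.  It is a thin convenience and
is not exercised by the test suite, which relies on the synthetic
generator instead.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .io import CSV_COLUMNS, MonthlySeries, series_from_table


def load_deposit(
    path,
    column_map: Mapping[str, str],
    defaults: Mapping[str, object] | None = None,
) -> dict[tuple[str, str, str], MonthlySeries]:
    """Read a deposited CSV whose columns differ only in naming.

    ``column_map`` maps canonical names (region, age_group, sex, year,
    month, ddd, population, days, incident_count) to the deposit's
    column names; ``defaults`` supplies constant values for canonical
    columns the deposit lacks (e.g. ``{"sex": "all"}``).
    """
    table = pd.read_csv(path)
    renamed = table.rename(columns={v: k for k, v in column_map.items()})
    for name, value in (defaults or {}).items():
        renamed[name] = value
    missing = [c for c in CSV_COLUMNS if c not in renamed.columns]
    if missing and missing != ["incident_count"]:
        raise KeyError(f"deposit is missing canonical columns: {missing}")
    if "incident_count" not in renamed.columns:
        renamed["incident_count"] = float("nan")
    return series_from_table(renamed[CSV_COLUMNS])
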