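"""Intervention regressors for the volume and incidence ITS analyses.

All columns are length-60 vectors indexed by study month (Jan 2018 = 1):

* ``volume_pulse`` — the March–May 2020 stockpiling shape: +a in March
  2020 and -b in April and May ("standard"); the "slovenia" variant
  mirrors it as (-b, -b, +a).  Defaults a=1, b=0.5 make the column
  zero-sum, so its coefficient reads as volume shifted into March from
  April–May.
* ``volume_ramp`` — 0 before June 2020, then increasing by one unit per
  month (1 at June 2020 up to 31 at December 2022); its coefficient is
  a change in slope.
* ``incidence_pulse`` — indicator of March–May 2020 (the expected
  temporary decline during the first lockdowns).
* ``incidence_ramp_plateau`` — ramp from June 2020 (1) to December 2021
  (19), held at 19 throughout 2022.
* ``incidence_ramp_2022`` — ramp over 2022 only: 1 at January 2022 up
  to 12 at December 2022.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import studycalendar as cal
from .errors import ValidationError

PULSE_VARIANTS = ("standard", "slovenia")


def _month_range() -> np.ndarray:
    return np.arange(1, cal.N_MONTHS + 1)


def build_volume_pulse(variant: str = "standard", a: float = 1.0, b: float = 0.5) -> np.ndarray:
    """The three-month stockpiling pulse over March–May 2020.

    ``standard``: (+a, -b, -b); ``slovenia``: (-b, -b, +a).
    """
    if variant not in PULSE_VARIANTS:
        raise ValidationError(f"unknown pulse variant {variant!r}")
    if not (a > 0 and b > 0):
        raise ValidationError("pulse shape parameters a, b must be positive")
    col = np.zeros(cal.N_MONTHS)
    if variant == "standard":
        col[cal.MARCH_2020 - 1 : cal.MARCH_2020 + 2] = (a, -b, -b)
    else:
        col[cal.MARCH_2020 - 1 : cal.MARCH_2020 + 2] = (-b, -b, a)
    return col


def build_volume_ramp() -> np.ndarray:
    """Ramp from June 2020 (1) to December 2022 (31); 0 before onset."""
    t = _month_range()
    return np.where(t >= cal.JUNE_2020, t - (cal.JUNE_2020 - 1), 0).astype(float)


def build_incidence_regressors() -> pd.DataFrame:
    """The three incidence regressors as a month-indexed DataFrame."""
    t = _month_range()
    pulse = ((t >= cal.MARCH_2020) & (t < cal.JUNE_2020)).astype(float)
    ramp_plateau = np.clip(t - (cal.JUNE_2020 - 1), 0, cal.DECEMBER_2021 - (cal.JUNE_2020 - 1)).astype(float)
    ramp_2022 = np.where(t > cal.DECEMBER_2021, t - cal.DECEMBER_2021, 0).astype(float)
    return pd.DataFrame(
        {
            "incidence_pulse": pulse,
            "incidence_ramp_plateau": ramp_plateau,
            "incidence_ramp_2022": ramp_2022,
        },
        index=pd.RangeIndex(1, cal.N_MONTHS + 1, name="month_index"),
    )


def build_regressor_matrix(
    variant: str = "standard", a: float = 1.0, b: float = 0.5
) -> pd.DataFrame:
    """All intervention columns, keyed by month index, for audit export."""
    out = build_incidence_regressors()
    out.insert(0, "volume_ramp", build_volume_ramp())
    out.insert(0, "volume_pulse", build_volume_pulse(variant, a, b))
    return out


def volume_design(variant: str = "standard", a: float = 1.0, b: float = 0.5) -> pd.DataFrame:
    """The two volume-ITS columns (pulse, ramp)."""
    return pd.DataFrame(
        {
            "volume_pulse": build_volume_pulse(variant, a, b),
            "volume_ramp": build_volume_ramp(),
        },
        index=pd.RangeIndex(1, cal.N_MONTHS + 1, name="month_index"),
    )
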