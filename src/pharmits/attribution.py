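"""Pandemic-attribution arithmetic from fitted ITS coefficients.

For volumes the ramp coefficient is a monthly rate of pandemic-related
change; its cumulative effect at December 2022 is rate x 31 (the ramp
value in the final month).  For incidence the cumulative change over
March 2020 – December 2022 sums each significant regressor's estimate
times its accumulated regressor values: 3 for the lockdown pulse
(three months at 1), 418 for the ramp-plateau (1+...+19 plus 19 x 12)
and 78 for the 2022 ramp (1+...+12).  Low/high estimates substitute the
95% CI bounds of each significant regressor; non-significant
regressors contribute nothing, so attribution is reported only when at
least one gating coefficient is significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .its import CoefficientEstimate, ITSFit

#: volume ramp value at December 2022 (months June 2020 .. December 2022)
RAMP_VALUE_DEC2022 = 31.0

#: accumulated regressor values over March 2020 – December 2022
INCIDENCE_MULTIPLIERS: dict[str, float] = {
    "incidence_pulse": 3.0,
    "incidence_ramp_plateau": 418.0,
    "incidence_ramp_2022": 78.0,
}


@dataclass(frozen=True)
class AttributionEstimate:
    """Middle/low/high cumulative pandemic-related change and its share.

    ``computed`` is False when no gating coefficient is significant at
    the 0.05 level; middle/low/high and share are then None (rendered
    as dashes in table output).
    """

    middle: float | None
    low: float | None
    high: float | None
    observed: float
    share_pct: float | None
    computed: bool

    def __post_init__(self) -> None:
        if self.computed:
            if not (self.low <= self.middle <= self.high):
                raise ValidationError("attribution bounds must satisfy low <= middle <= high")


def _coeff(fit, name: str) -> CoefficientEstimate:
    coeffs = fit.coefficients if isinstance(fit, ITSFit) else fit
    if name not in coeffs:
        raise ValidationError(f"fit does not contain coefficient {name!r}")
    return coeffs[name]


def share_of_observed(middle: float, observed: float) -> float:
    """Share (%) of an attributed change on the observed value."""
    if observed <= 0:
        raise UndefinedMetricError("observed value must be positive for a share")
    return middle / observed * 100.0


def volume_attribution(
    fit: ITSFit | Mapping[str, CoefficientEstimate],
    observed_dec2022: float,
    ramp_name: str = "volume_ramp",
) -> AttributionEstimate:
    """End-of-period (December 2022) pandemic-related change in DDD/TID.

    Computed only when the ramp coefficient is significant (p < 0.05):
    middle = rate x 31, low/high = CI bounds x 31, share = middle /
    observed x 100.
    """
    if observed_dec2022 <= 0:
        raise UndefinedMetricError("observed December 2022 DDD/TID must be positive")
    c = _coeff(fit, ramp_name)
    if not c.significant:
        return AttributionEstimate(None, None, None, observed_dec2022, None, False)
    middle = c.estimate * RAMP_VALUE_DEC2022
    low = c.ci_low * RAMP_VALUE_DEC2022
    high = c.ci_high * RAMP_VALUE_DEC2022
    return AttributionEstimate(
        middle=middle,
        low=low,
        high=high,
        observed=observed_dec2022,
        share_pct=share_of_observed(middle, observed_dec2022),
        computed=True,
    )


def incidence_attribution(
    fit: ITSFit | Mapping[str, CoefficientEstimate],
    observed_total: float,
    joint: bool = False,
) -> AttributionEstimate:
    """Cumulative pandemic-related incidence change over 3/2020–12/2022.

    Sums estimate x multiplier over the significant regressors among
    pulse, ramp-plateau and 2022 ramp; low/high substitute each
    significant regressor's CI bounds (so the low–high range may
    include 0).  With ``joint=True`` the low/high bounds instead use
    the covariance-based 95% CI of the summed linear combination
    (requires an :class:`ITSFit` carrying a coefficient covariance).
    """
    if observed_total <= 0:
        raise UndefinedMetricError("observed cumulative incidence must be positive")
    coeffs = {name: _coeff(fit, name) for name in INCIDENCE_MULTIPLIERS}
    significant = {n: c for n, c in coeffs.items() if c.significant}
    if not significant:
        return AttributionEstimate(None, None, None, observed_total, None, False)
    middle = sum(c.estimate * INCIDENCE_MULTIPLIERS[n] for n, c in significant.items())
    if joint:
        if not isinstance(fit, ITSFit) or fit.cov is None:
            raise ValidationError("joint CI requires an ITSFit with covariance")
        names = list(significant)
        w = np.array([INCIDENCE_MULTIPLIERS[n] for n in names])
        var = float(w @ fit.cov.loc[names, names].to_numpy() @ w)
        half = 1.959963984540054 * np.sqrt(max(var, 0.0))
        low, high = middle - half, middle + half
    else:
        low = sum(c.ci_low * INCIDENCE_MULTIPLIERS[n] for n, c in significant.items())
        high = sum(c.ci_high * INCIDENCE_MULTIPLIERS[n] for n, c in significant.items())
    return AttributionEstimate(
        middle=middle,
        low=low,
        high=high,
        observed=observed_total,
        share_pct=share_of_observed(middle, observed_total),
        computed=True,
    )


# -- table export ------------------------------------------------------


def _fmt(value: float | None, decimals: int) -> str:
    return "-" if value is None else f"{value:.{decimals}f}"


def volume_table(rows: Mapping[str, tuple[float, AttributionEstimate]]) -> pd.DataFrame:
    """One row per region: observed Dec 2022 value and attribution.

    ``rows`` maps region -> (observed value, estimate).  DDD/TID
    quantities use 3 decimals, shares 1 decimal; dashes mark
    non-computed cells.
    """
    out = []
    for region, (observed, est) in rows.items():
        out.append(
            {
                "region": region,
                "observed_dec2022": f"{observed:.3f}",
                "middle": _fmt(est.middle, 3),
                "low": _fmt(est.low, 3),
                "high": _fmt(est.high, 3),
                "share_pct": _fmt(est.share_pct, 1),
            }
        )
    return pd.DataFrame(out)


def incidence_table(
    rows: Mapping[tuple[str, str], tuple[float, AttributionEstimate]]
) -> pd.DataFrame:
    """One row per (region, sex): observed cumulative incidence and attribution."""
    out = []
    for (region, sex), (observed, est) in rows.items():
        out.append(
            {
                "region": region,
                "sex": sex,
                "observed_total": f"{observed:.1f}",
                "middle": _fmt(est.middle, 1),
                "low": _fmt(est.low, 1),
                "high": _fmt(est.high, 1),
                "share_pct": _fmt(est.share_pct, 1),
            }
        )
    return pd.DataFrame(out)
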