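"""End-to-end convenience runners: series -> metrics -> fit -> attribution."""

from __future__ import annotations

from dataclasses import dataclass

from .attribution import AttributionEstimate, incidence_attribution, volume_attribution
from .io import MonthlySeries
from .its import ITSFit, Orders, select_orders, fit_its
from .metrics import compute_incidence, monthly_dddtid, monthly_incidence
from .regressors import build_incidence_regressors, volume_design
from . import studycalendar as cal


@dataclass
class AnalysisResult:
    """Fit plus attribution for one series."""

    fit: ITSFit
    attribution: AttributionEstimate
    observed: float


def run_volume_analysis(
    series: MonthlySeries,
    pulse_variant: str = "standard",
    orders: Orders | None = None,
) -> AnalysisResult:
    """Volume ITS for one series: monthly DDD/TID, pulse + ramp regressors,
    SARIMA fit (orders auto-selected unless given) and the December 2022
    pandemic attribution."""
    y = monthly_dddtid(series)
    X = volume_design(pulse_variant)
    if orders is None:
        orders = select_orders(y.to_numpy(), X)
    fit = fit_its(y.to_numpy(), X, orders, outcome="dddtid")
    observed = float(y.loc[cal.DECEMBER_2022])
    return AnalysisResult(fit=fit, attribution=volume_attribution(fit, observed), observed=observed)


def run_incidence_analysis(
    series: MonthlySeries,
    orders: Orders | None = None,
) -> AnalysisResult:
    """Incidence ITS for one series: monthly incidence per 100,000, the
    three pandemic regressors, SARIMA fit and the cumulative 3/2020–12/2022
    attribution (observed total = sum of monthly incidences over the
    pandemic period)."""
    y = monthly_incidence(series)
    X = build_incidence_regressors()
    if orders is None:
        orders = select_orders(y.to_numpy(), X)
    fit = fit_its(y.to_numpy(), X, orders, outcome="incidence")
    observed = sum(
        compute_incidence(series, m).incidence for m in cal.COVID_RANGE
    )
    return AnalysisResult(
        fit=fit, attribution=incidence_attribution(fit, observed), observed=observed
    )
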