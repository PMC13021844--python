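import numpy as np
import pytest
from hypothesis import settings

import pharmits as ph
from pharmits import studycalendar as cal

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def flat_series() -> ph.MonthlySeries:
    """Constant series: v = 30 DDD/TID every month, population 100,000."""
    days = np.array([cal.days_in_month(i) for i in range(1, 61)])
    pop = np.full(60, 100_000)
    ddd = 30.0 / 1000.0 * days * pop
    return ph.MonthlySeries.from_arrays("testland", "all", "all", ddd, pop, days)


@pytest.fixture
def counted_series(flat_series) -> ph.MonthlySeries:
    """Flat series with 50 incident recipients every month."""
    s = flat_series
    s.data["incident_count"] = 50.0
    return s


def make_noiseless_config(**overrides) -> ph.SimulationConfig:
    base = dict(
        regions=("r1",),
        age_groups=("18-44",),
        sexes=("female",),
        innovation_sd=0.0,
        seasonal_amplitude=0.0,
        incidence_seasonal_amplitude=0.0,
        pulse_effect=0.0,
        ramp_slope=0.0,
        incidence_pulse_effect=0.0,
        plateau_slope=0.0,
        slope_2022=0.0,
        trend_slope=0.0,
        incidence_trend=0.0,
    )
    base.update(overrides)
    return ph.SimulationConfig(**base)
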