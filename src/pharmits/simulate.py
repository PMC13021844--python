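"""Synthetic stratified dispensing cohorts with known pandemic effects.

The generator emulates the statistical structure the ITS analysis
assumes: a 60-month series per region and stratum with linear trend,
one annual sinusoid, ARMA noise, a three-month pulse at pandemic onset
(March–May 2020) and post-June-2020 ramp effects.  Volumes are
continuous (Gaussian ARMA noise around the mean structure, expressed
in DDD/TID and inverted to dispensed DDD totals via population and
days); incident counts are Poisson around an expected incidence per
100,000.  Person-level event tables add a new-user/persistence process
with a pre-2018 burn-in so the 12-month washout rule is exercisable
from January 2018.

Everything is reproducible from ``SimulationConfig.seed``; per-stratum
streams are spawned deterministically so adding strata does not change
existing ones.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import studycalendar as cal
from .errors import ValidationError
from .io import MonthlySeries
from .regressors import build_incidence_regressors, build_volume_pulse, build_volume_ramp

logger = logging.getLogger(__name__)

AGE_GROUPS = ("0-17", "18-44", "45-64", "65-74", "75+")
SEXES = ("female", "male")

#: paper-like DDD/TID baselines per age group (low in children, high in old age)
DEFAULT_BASELINE_VOLUME = {
    "0-17": 27.0,
    "18-44": 60.0,
    "45-64": 110.0,
    "65-74": 160.0,
    "75+": 210.0,
}
#: incidence per 100,000 baselines, lowest in the youngest stratum
DEFAULT_BASELINE_INCIDENCE = {
    "0-17": 25.0,
    "18-44": 60.0,
    "45-64": 75.0,
    "65-74": 85.0,
    "75+": 100.0,
}
ATC_CODES = ("N06AB06", "N06AB10", "N06AX16", "N06AA09")


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic cohort.

    Volume units are DDD/TID; incidence units are recipients per
    100,000; trend and ramp slopes are per month.
    """

    regions: tuple[str, ...] = ("region_a", "region_b")
    age_groups: tuple[str, ...] = AGE_GROUPS
    sexes: tuple[str, ...] = SEXES

    # volume outcome (DDD/TID scale)
    baseline_volume: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_VOLUME)
    )
    sex_volume_factor: Mapping[str, float] = field(
        default_factory=lambda: {"female": 1.25, "male": 0.75, "all": 1.0}
    )
    trend_slope: float = 0.15
    seasonal_amplitude: float = 2.0
    seasonal_phase: float = 0.0
    ar: tuple[float, ...] = (0.5,)
    ma: tuple[float, ...] = ()
    innovation_sd: float = 1.0
    pulse_effect: float = 4.0
    pulse_variant: str = "standard"
    ramp_slope: float = 0.1

    # incidence outcome (per 100,000 scale)
    baseline_incidence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_INCIDENCE)
    )
    sex_incidence_factor: Mapping[str, float] = field(
        default_factory=lambda: {"female": 1.3, "male": 0.7, "all": 1.0}
    )
    incidence_trend: float = 0.05
    incidence_seasonal_amplitude: float = 3.0
    incidence_pulse_effect: float = -8.0
    plateau_slope: float = 0.6
    slope_2022: float = 0.2

    populations: int | Mapping[tuple[str, str], int] = 100_000

    # person-level event process
    event_incidence: float = 50.0  # new starters per 100,000 per month
    event_population: int = 20_000
    persistence: float = 0.85
    restart_prob: float = 0.01
    burnin_months: int = 18

    seed: int = 0

    def __post_init__(self) -> None:
        if self.innovation_sd < 0:
            raise ValidationError("innovation SD must be non-negative")
        if not 0.0 <= self.persistence < 1.0:
            raise ValidationError("persistence must lie in [0, 1)")
        if self.burnin_months < 12:
            raise ValidationError("burn-in must cover at least 12 months for the washout rule")
        for key, pop in self._population_items():
            if pop <= 0:
                raise ValidationError(f"population for stratum {key} must be positive")
        if self.event_population <= 0:
            raise ValidationError("event population must be positive")

    def _population_items(self):
        if isinstance(self.populations, Mapping):
            return list(self.populations.items())
        return [(("*", "*"), int(self.populations))]

    def population_for(self, age_group: str, sex: str) -> int:
        if isinstance(self.populations, Mapping):
            try:
                return int(self.populations[(age_group, sex)])
            except KeyError:
                raise ValidationError(f"no population for stratum {(age_group, sex)}")
        return int(self.populations)

    def strata(self) -> list[tuple[str, str]]:
        return [(a, s) for a in self.age_groups for s in self.sexes]


def _child_rng(seed: int, *labels: str) -> np.random.Generator:
    # stable per-stratum stream: labels hashed with a process-independent digest
    key = [
        int.from_bytes(hashlib.sha256(lbl.encode("utf-8")).digest()[:4], "little")
        for lbl in labels
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _arma_noise(rng: np.random.Generator, config: SimulationConfig, n: int) -> np.ndarray:
    if config.innovation_sd == 0:
        return np.zeros(n)
    from statsmodels.tsa.arima_process import arma_generate_sample

    ar = np.r_[1.0, -np.asarray(config.ar, dtype=float)]
    ma = np.r_[1.0, np.asarray(config.ma, dtype=float)]
    return arma_generate_sample(
        ar,
        ma,
        nsample=n,
        scale=config.innovation_sd,
        distrvs=rng.standard_normal,
        burnin=200,
    )


def _seasonal(amplitude: float, phase: float, t: np.ndarray) -> np.ndarray:
    return amplitude * np.sin(2.0 * np.pi * (t - phase) / 12.0)


def expected_volume(config: SimulationConfig, age_group: str, sex: str) -> np.ndarray:
    """Noise-free mean DDD/TID path for one stratum (the generator's truth)."""
    t = np.arange(1, cal.N_MONTHS + 1, dtype=float)
    base = config.baseline_volume[age_group] * config.sex_volume_factor[sex]
    mean = (
        base
        + config.trend_slope * t
        + _seasonal(config.seasonal_amplitude, config.seasonal_phase, t)
        + config.pulse_effect * build_volume_pulse(config.pulse_variant)
        + config.ramp_slope * build_volume_ramp()
    )
    return mean


def expected_incidence(config: SimulationConfig, age_group: str, sex: str) -> np.ndarray:
    """Noise-free expected incidence per 100,000 for one stratum."""
    t = np.arange(1, cal.N_MONTHS + 1, dtype=float)
    reg = build_incidence_regressors()
    base = config.baseline_incidence[age_group] * config.sex_incidence_factor[sex]
    mean = (
        base
        + config.incidence_trend * t
        + _seasonal(config.incidence_seasonal_amplitude, config.seasonal_phase, t)
        + config.incidence_pulse_effect * reg["incidence_pulse"].to_numpy()
        + config.plateau_slope * reg["incidence_ramp_plateau"].to_numpy()
        + config.slope_2022 * reg["incidence_ramp_2022"].to_numpy()
    )
    neg = int((mean < 0).sum())
    if neg:
        logger.warning("expected incidence negative in %d months; truncated to 0", neg)
        mean = np.clip(mean, 0.0, None)
    return mean


def simulate_volume_series(config: SimulationConfig) -> dict[tuple[str, str, str], MonthlySeries]:
    """Simulate dispensed-DDD monthly series for every region and stratum.

    The DDD/TID outcome is mean structure + ARMA noise, truncated at 0
    (truncations are logged), then inverted to dispensed DDD totals
    with the stratum's population and calendar days.
    """
    out: dict[tuple[str, str, str], MonthlySeries] = {}
    days = np.array([cal.days_in_month(i) for i in range(1, cal.N_MONTHS + 1)])
    truncated = 0
    for region in config.regions:
        for age_group, sex in config.strata():
            rng = _child_rng(config.seed, "volume", region, age_group, sex)
            v = expected_volume(config, age_group, sex) + _arma_noise(rng, config, cal.N_MONTHS)
            truncated += int((v < 0).sum())
            v = np.clip(v, 0.0, None)
            pop = config.population_for(age_group, sex)
            u = v / 1000.0 * days * pop
            series = MonthlySeries.from_arrays(
                region=region,
                age_group=age_group,
                sex=sex,
                ddd=u,
                population=np.full(cal.N_MONTHS, pop),
                days=days,
            )
            out[series.key] = series
    if truncated:
        logger.warning("volume simulation truncated %d negative values to 0", truncated)
    return out


def simulate_incidence_series(config: SimulationConfig) -> pd.DataFrame:
    """Simulate monthly incident counts per region and stratum.

    Counts are Poisson with mean expected_incidence x population /
    100,000.  Returns a long DataFrame (region, age_group, sex,
    month_index, incident_count, population, expected_incidence).
    """
    rows = []
    for region in config.regions:
        for age_group, sex in config.strata():
            rng = _child_rng(config.seed, "incidence", region, age_group, sex)
            mean = expected_incidence(config, age_group, sex)
            pop = config.population_for(age_group, sex)
            lam = mean * pop / 100000.0
            counts = rng.poisson(lam)
            rows.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "age_group": age_group,
                        "sex": sex,
                        "month_index": np.arange(1, cal.N_MONTHS + 1),
                        "incident_count": counts,
                        "population": pop,
                        "expected_incidence": mean,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> dict[tuple[str, str, str], MonthlySeries]:
    """Volume series with incident counts attached (full synthetic cohort)."""
    series = simulate_volume_series(config)
    counts = simulate_incidence_series(config)
    for (region, age_group, sex), grp in counts.groupby(["region", "age_group", "sex"]):
        s = series[(region, age_group, sex)]
        s.data["incident_count"] = (
            grp.set_index("month_index")["incident_count"].astype(float).reindex(s.data.index)
        )
    return series


def simulate_person_events(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Person-level dispensing histories plus the generator's incident log.

    Per region, new starters arrive Poisson(event_incidence x
    event_population / 100,000) each month from ``burnin_months``
    before January 2018 through December 2022; an active person
    redispenses next month with probability ``persistence`` and a
    stopped person restarts with probability ``restart_prob``.  The log
    counts, per study month, dispensing persons whose previous
    dispensing (tracked incrementally during generation) was more than
    12 months earlier or absent — the bookkeeping oracle for the
    washout rule.

    Returns (events, log): events has columns person_id,
    dispensing_date, atc_code, region; log has region, month_index,
    incident_count.
    """
    base_abs = cal.START_YEAR * 12 + cal.START_MONTH
    end_abs = cal.END_YEAR * 12 + cal.END_MONTH
    start_abs = base_abs - config.burnin_months
    rate = config.event_incidence * config.event_population / 100000.0

    all_events = []
    log_rows = []
    for region in config.regions:
        rng = _child_rng(config.seed, "events", region)
        next_id = 0
        active: set[int] = set()
        stopped: set[int] = set()
        last_disp: dict[int, int] = {}
        for am in range(start_abs, end_abs + 1):
            dispensers = []
            still_active = set()
            for pid in sorted(active):
                if rng.random() < config.persistence:
                    dispensers.append(pid)
                    still_active.add(pid)
                else:
                    stopped.add(pid)
            restarted = {pid for pid in sorted(stopped) if rng.random() < config.restart_prob}
            stopped -= restarted
            still_active |= restarted
            dispensers.extend(sorted(restarted))
            n_new = rng.poisson(rate)
            for _ in range(n_new):
                pid = next_id
                next_id += 1
                dispensers.append(pid)
                still_active.add(pid)
            active = still_active

            year, month = (am - 1) // 12, am - ((am - 1) // 12) * 12
            date = pd.Timestamp(year=year, month=month, day=15)
            incident_here = 0
            for pid in dispensers:
                prev = last_disp.get(pid)
                if prev is None or am - prev > 12:
                    incident_here += 1
                last_disp[pid] = am
                all_events.append(
                    {
                        "person_id": f"{region}-{pid}",
                        "dispensing_date": date,
                        "atc_code": ATC_CODES[pid % len(ATC_CODES)],
                        "region": region,
                    }
                )
            if base_abs <= am <= end_abs:
                log_rows.append(
                    {
                        "region": region,
                        "month_index": am - base_abs + 1,
                        "incident_count": incident_here,
                    }
                )
    events = pd.DataFrame(all_events, columns=["person_id", "dispensing_date", "atc_code", "region"])
    log = pd.DataFrame(log_rows, columns=["region", "month_index", "incident_count"])
    return events, log
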