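# pharmits

Interrupted time-series (ITS) analysis of monthly outpatient drug-dispensing
data, built for pharmacoepidemiologists studying how the COVID-19 pandemic
changed antidepressant (ATC N06A) utilization across European regions — and
for anyone running the same design on other drug classes or interventions.

## What it computes

**Utilization metrics.** Dispensed volume of a period *p* (month or quarter)
in DDD per 1000 inhabitants per day,

```
v_p = (Σ_m u_{m,p}) / (d_p · n_p) · 1000,
```

with `u` the dispensed DDD totals, `d_p` days in the period and `n_p` the
population; treatment incidence per 100,000,

```
incidence_p = (Σ k_p) / (Σ n_p) · 100000,
```

where an incident recipient in month *m* had no N06A dispensing in the 12
calendar months before *m* (derivable from person-level event tables);
and relative quarterly change versus the pre-pandemic base year 2019,
`Δ_{q,y} = (value_{q,y} / value_{q,2019} − 1) · 100`.

**The ITS model.** Each 60-month outcome series (January 2018 – December
2022) is regressed on an intercept, a deterministic linear trend and
intervention regressors, with seasonal ARIMA (p,d,q)(P,D,Q)₁₂ errors:

* volumes: a three-month stockpiling pulse over March–May 2020
  (`+1, −½, −½`; a mirrored variant for regions that dipped first and
  rebounded in May) and a ramp rising one unit per month from June 2020
  (31 at December 2022), whose coefficient is the monthly rate of
  pandemic-related slope change;
* incidence (ages 0–17): a March–May 2020 lockdown indicator, a ramp from
  June 2020 that plateaus at its December 2021 value (19) through 2022,
  and a separate ramp over 2022.

Coefficients are tested with the z-test at the 0.05 level; residuals are
checked with the Ljung-Box test (maximum lag 12) and KPSS tests for level
and trend stationarity. Orders can be fixed or selected by a bounded
stepwise AICc search.

**Attribution.** For a significant volume ramp, the pandemic-related change
at December 2022 is `rate × 31` with low/high bounds from the 95% CI, and
its share of the observed December 2022 value. For incidence, the
cumulative change over 3/2020–12/2022 sums each significant regressor's
estimate times its accumulated values (pulse × 3, plateau ramp × 418,
2022 ramp × 78).

**Synthetic cohorts.** `pharmits.simulate` generates stratified (five age
groups × sex × regions) dispensing and incidence series with trend, annual
seasonality, ARMA noise and known injected pandemic effects, plus
person-level dispensing histories with a pre-2018 burn-in, so the whole
pipeline is testable without access to registry data.

## Worked example

```python
import pharmits as ph

cfg = ph.SimulationConfig(regions=("exampleland",), age_groups=("18-44",),
                          sexes=("female",), ramp_slope=0.2, seed=42)
series = ph.simulate_volume_series(cfg)
s = series[("exampleland", "18-44", "female")]
res = ph.run_volume_analysis(s)          # orders auto-selected
print("selected orders:", res.fit.orders)
print(res.fit.summary_table().round(4).to_string(index=False))
a = res.attribution
print(f"observed Dec 2022: {res.observed:.3f} DDD/TID")
print(f"pandemic-related change by Dec 2022: {a.middle:.3f} "
      f"(95% CI {a.low:.3f} to {a.high:.3f}) DDD/TID")
print(f"share of observed value: {a.share_pct:.1f}%")
```

prints

```
selected orders: (1,0,0)(2,1,0)[12]
        name  estimate     se       z     p  ci_low  ci_high
       trend    0.1806 0.0309  5.8405 0.000  0.1200   0.2412
volume_pulse    5.0132 0.7058  7.1032 0.000  3.6299   6.3965
 volume_ramp    0.1268 0.0516  2.4580 0.014  0.0257   0.2279
       ar.L1    0.5733 0.1292  4.4360 0.000  0.3200   0.8266
    ar.S.L12   -0.7459 0.1459 -5.1142 0.000 -1.0318  -0.4601
    ar.S.L24   -0.5681 0.1347 -4.2182 0.000 -0.8321  -0.3042
      sigma2    0.8455 0.1997  4.2327 0.000  0.4540   1.2369
observed Dec 2022: 88.184 DDD/TID
pandemic-related change by Dec 2022: 3.931 (95% CI 0.797 to 7.065) DDD/TID
share of observed value: 4.5%
```

The ramp coefficient 0.1268 DDD/TID/month is the estimated pandemic-related
slope change; multiplied by 31 (the ramp's December 2022 value) it gives the
cumulative change 3.931 DDD/TID, 4.5% of the observed December 2022 level.
The generator injected a slope of 0.2 (cumulative 6.2), which lies inside
the 95% interval. `ph.diagnose(res.fit)` reports the Ljung-Box and KPSS
checks for the same fit — for this seed the Ljung-Box test still flags
residual autocorrelation (p = 0.006), exactly the situation the diagnostic
exists to surface.

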