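# Methods

## Study frame

All series live on a fixed 60-month calendar, January 2018 (index 1) to
December 2022 (index 60), split into a pre-pandemic period (indices 1–26,
through February 2020) and a pandemic period (indices 27–60, March 2020
onward). Series are stratified by region, age group (0–17, 18–44, 45–64,
65–74, 75+, or "all") and sex (female, male, all); the on-disk format is a
long CSV with one row per region/stratum/month carrying dispensed DDD
totals, population, days in the month and (optionally) incident-recipient
counts. Days per month are stored as data, not recomputed: registry
extracts occasionally use accounting conventions, so a mismatch with the
civil calendar warns rather than fails. Unknown stratum labels are errors —
silent pass-through of typos would corrupt downstream grouping.

## Metrics

DDD/TID for a period is Σu / (d·n) · 1000. For multi-month periods the
population n is the mean of the monthly populations and d the exact sum of
days; this reduces to the single-population formula when population is
constant within the period, which is how registry extracts usually report
it. Monthly population is stored as given — any interpolation of mid-year
revisions is the data producer's responsibility.

Incidence per 100,000 pools counts over population month-by-month
(Σk / Σn · 100000). The washout rule operates at calendar-month
resolution: a person is incident in month m iff they have an N06A
dispensing in m and none in months m−12..m−1. Day-level washout is not
reconstructible from monthly data, so month-level is the package-wide
convention; a person dispensing several times within their incident month
counts once. Deriving counts from person-level events requires 12 months
of history before the first requested month and fails loudly otherwise.

Relative change compares each quarter to the same quarter of 2019 and is
exactly 0 for 2019 by construction. Values are kept unrounded internally;
table exports round relative changes to 0 decimals, DDD/TID quantities to
3 and shares/incidence to 1.

## Intervention regressors

The volume pulse is (+a, −b, −b) over March–May 2020 with defaults a=1,
b=0.5, a zero-sum shape so its coefficient reads as volume shifted into
March from the following two months; the mirrored (−b, −b, +a) variant
covers regions that dipped first and rebounded in May. The magnitudes are
configurable because only the sign pattern and timing are fixed by the
design. The volume ramp increases by 1 per month from June 2020, reaching
31 in December 2022; with a deterministic linear trend always in the
model, its coefficient is a change in slope and its cumulative effect at
month t is coefficient × ramp(t).

The incidence design uses a plain indicator for March–May 2020 (a level
drop during lockdowns, not a redistribution, hence not zero-sum), a ramp
from June 2020 that freezes at 19 from December 2021 through 2022, and a
separate 1..12 ramp over 2022. Accumulated values over the pandemic window
are 3, 418 (=1+…+19 + 19·12) and 78 (=1+…+12); these multipliers drive the
attribution arithmetic.

## ITS estimation

The model is a regression on [intercept, linear trend, regressors] with
SARIMA(p,d,q)(P,D,Q)₁₂ errors, estimated by Gaussian maximum likelihood
(statsmodels state-space SARIMAX). Columns that differencing annihilates —
the intercept whenever d≥1 or D≥1, the trend when d≥2 — are dropped
automatically since their effect is absorbed; the remaining design is
rank-checked after differencing and collinear columns are named in the
error. With all orders zero the fit is closed-form least squares with the
ML variance convention, so no optimizer is involved. Standard errors come
from the observed information matrix; coefficient tests are two-sided
z-tests and CIs are estimate ± 1.96·SE throughout. Optimization retries
once with a derivative-free pass if L-BFGS does not converge, and a run
that terminates at a numerically flat gradient is accepted as converged.

Order selection, when not fixed by the user, is a bounded stepwise AICc
search: d (≤2) from repeated KPSS level tests on the residuals of the
deterministic regression, D∈{0,1} from the STL seasonal-strength
heuristic (threshold 0.64), then a hill-climb over p,q≤3 and P,Q≤2 with
the regressors included in every candidate. Like any AIC-family selector
at n=60, it admits spurious low-order ARMA terms on truly white series a
substantial fraction of the time; selection is therefore a convenience,
and analyses meant to be compared across strata should fix orders.

Diagnostics are pure functions of the residual vector (after discarding
the d + 12·D pre-sample values): the Ljung-Box statistic at lags 1..12 —
by default without subtracting fitted ARMA parameters from the degrees of
freedom; a `model_df` option does — and KPSS with level and trend nulls.
KPSS p-values are interpolated from the standard critical-value tables and
clamped (with a flag) outside the tabulated 0.01–0.10 range.

### Calibration at n = 60

Sixty observations is short for ML inference with estimated ARMA
parameters. In the package's own simulations (AR(1) noise, φ=0.5), the
nominal 95% z-interval for the ramp coefficient covers the truth ~85–88%
of the time and the null rejection rate is ~9–10% rather than 5%; about
two points of that gap come from using z rather than t critical values
with the ML variance, the rest from estimating the AR parameter. This is
a property of the prescribed inference, not of the optimizer, and users
should read borderline p-values accordingly. The acceptance script
recomputes these rates so the calibration is visible rather than hidden.

## Attribution

Volume: if the ramp rate is significant, middle = rate × 31 and low/high
are the CI bounds × 31, with the share middle/observed(Dec 2022)·100;
otherwise no estimate is reported (rendered as dashes). Incidence: middle
sums estimate × multiplier over the significant regressors only, and
low/high substitute each significant regressor's CI bounds — a deliberate
per-regressor propagation, so the low–high range can include 0; a
covariance-based interval for the same linear combination is available
via `joint=True`. Significance gating is strict p < 0.05. The pulse's
contribution (estimate × 3) is validated against noiseless synthetic
oracles, where the recovered cumulative change equals the injected
pulse·3 + slope·418 + slope2022·78 (volumes: slope·31) exactly.

## Synthetic data generator

Each stratum's volume path is baseline + trend·t + one annual sinusoid +
pulse and ramp effects + Gaussian ARMA noise, truncated at 0 (truncations
are logged), then inverted to dispensed DDD totals through the DDD/TID
formula with the stratum's population and calendar days — so the metrics
module recovers the injected path exactly when noise is off. Defaults:
age-group baselines 27–210 DDD/TID (low in children, high in old age),
female/male factors 1.25/0.75, trend 0.15 DDD/TID per month, seasonal
amplitude 2, AR(1) φ=0.5 with innovation SD 1, pulse +4 DDD/TID, ramp
slope 0.1 — levels and growth chosen to span the observed range of
European antidepressant utilization series. Incident counts are Poisson
around expected incidence × population/100,000, with baselines lowest in
the 0–17 stratum (25/100,000/month), a −8 lockdown dip, plateau-ramp
slope 0.6 and 2022 slope 0.2. Gaussian-ARMA volumes and Poisson counts
are modelling conveniences, not claims about registry noise; the
generator also omits policy timelines, reimbursement differences and
population drift, so passing tests demonstrate estimator correctness
under the assumed structure, not robustness to real-world artefacts.

Person-level histories are generated with new starters arriving at a
configured monthly incidence, monthly redispensing with probability
`persistence` (default 0.85), rare restarts (0.01/month) and an 18-month
pre-2018 burn-in; the generator tracks each person's previous dispensing
month as it goes, so its incident log is an independent bookkeeping
oracle for the washout derivation.

Per-stratum random streams are spawned from the seed with stable
label-hashed spawn keys: adding strata or regions never changes existing
series.

## Problem sizes

Simulation-based tests use 200 replicates for recovery/size/coverage,
500 for diagnostic calibration and 100 random tables for the washout
oracle; the acceptance script uses 100/300 replicates for the same
studies. All series are the study's native 60 months.

## Known limitations

No day-level washout; no joint (covariance-aware) default interval for
the incidence attribution; AICc stepwise selection overfits short white
series; z-based CIs are anticonservative at n=60 as quantified above; the
loader for externally deposited tables (`pharmits.external`) is a thin
column-mapping shim, not a schema-aware parser, and is untested against
any real deposit.
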