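"""Seasonal ARIMA interrupted-time-series fitting and diagnostics.

A monthly outcome (DDD/TID or incidence per 100,000) is modelled as a
regression on an intercept, a deterministic linear trend and the
intervention regressors, with SARIMA(p,d,q)(P,D,Q)_12 errors.  Including
the deterministic trend makes the ramp coefficient a change in slope.
Coefficient significance uses the z-test at the 0.05 level; model
quality is checked with the Ljung-Box test (maximum lag 12) and the
KPSS test for level and trend stationarity of the residuals.

Exogenous columns that a model's differencing annihilates (the
intercept under d >= 1 or D >= 1, the linear trend under d >= 2) are
dropped automatically: their effect is absorbed by the differencing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .errors import (
    DesignError,
    FitError,
    InsufficientResidualsError,
    SelectionError,
)

SEASONAL_PERIOD = 12
ALPHA = 0.05
_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class Orders:
    """SARIMA orders (p,d,q)(P,D,Q) with seasonal period 12."""

    p: int = 0
    d: int = 0
    q: int = 0
    P: int = 0
    D: int = 0
    Q: int = 0

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)

    @property
    def seasonal_order(self) -> tuple[int, int, int, int]:
        return (self.P, self.D, self.Q, SEASONAL_PERIOD)

    @property
    def is_plain_regression(self) -> bool:
        return not any((self.p, self.d, self.q, self.P, self.D, self.Q))

    def __str__(self) -> str:
        return f"({self.p},{self.d},{self.q})({self.P},{self.D},{self.Q})[12]"


@dataclass(frozen=True)
class CoefficientEstimate:
    """One regression coefficient with its z-test and 95% CI."""

    estimate: float
    se: float
    z: float
    pvalue: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_estimate_se(cls, estimate: float, se: float) -> "CoefficientEstimate":
        z = estimate / se if se > 0 else np.inf * np.sign(estimate)
        p = 2.0 * stats.norm.sf(abs(z))
        return cls(estimate, se, z, p, estimate - _Z975 * se, estimate + _Z975 * se)

    @classmethod
    def from_ci(cls, estimate: float, ci_low: float, ci_high: float) -> "CoefficientEstimate":
        """Reconstruct from a printed estimate and its 95% CI bounds."""
        se = (ci_high - ci_low) / (2 * _Z975)
        z = estimate / se if se > 0 else np.inf * np.sign(estimate)
        p = 2.0 * stats.norm.sf(abs(z))
        return cls(estimate, se, z, p, ci_low, ci_high)

    @property
    def significant(self) -> bool:
        return self.pvalue < ALPHA


@dataclass
class ITSFit:
    """A fitted interrupted-time-series model."""

    outcome: str
    orders: Orders
    coefficients: dict[str, CoefficientEstimate]
    loglik: float
    aicc: float
    residuals: np.ndarray = field(repr=False)
    nobs: int
    dropped_columns: tuple[str, ...] = ()
    cov: pd.DataFrame | None = field(default=None, repr=False)

    def summary_table(self) -> pd.DataFrame:
        """One row per coefficient: name, estimate, SE, z, p, CI bounds."""
        rows = [
            {
                "name": name,
                "estimate": c.estimate,
                "se": c.se,
                "z": c.z,
                "p": c.pvalue,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
            }
            for name, c in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual diagnostics at the 0.05 level."""

    ljung_box_stat: float
    ljung_box_pvalue: float
    ljung_box_pass: bool
    kpss_level_stat: float
    kpss_level_pvalue: float
    kpss_level_pass: bool
    kpss_trend_stat: float
    kpss_trend_pvalue: float
    kpss_trend_pass: bool
    kpss_level_clamped: bool = False
    kpss_trend_clamped: bool = False


# -- design handling ---------------------------------------------------


def _as_design(X, n: int, include_trend: bool) -> pd.DataFrame:
    """Assemble [const, trend, X] as a named DataFrame of length n."""
    if X is None:
        Xdf = pd.DataFrame(index=pd.RangeIndex(1, n + 1))
    elif isinstance(X, pd.DataFrame):
        Xdf = X.reset_index(drop=True)
        Xdf.index = pd.RangeIndex(1, n + 1)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != n:
            X = X.T
        Xdf = pd.DataFrame(
            X, columns=[f"x{j}" for j in range(X.shape[1])], index=pd.RangeIndex(1, n + 1)
        )
    design = pd.DataFrame(index=Xdf.index)
    design["const"] = 1.0
    if include_trend:
        design["trend"] = np.arange(1, n + 1, dtype=float)
    for c in Xdf.columns:
        design[c] = Xdf[c].to_numpy(dtype=float)
    return design


def _difference(col: np.ndarray, d: int, D: int) -> np.ndarray:
    x = np.asarray(col, dtype=float)
    for _ in range(D):
        x = x[SEASONAL_PERIOD:] - x[:-SEASONAL_PERIOD]
    for _ in range(d):
        x = np.diff(x)
    return x


def _prune_and_check(design: pd.DataFrame, orders: Orders) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Drop columns annihilated by differencing; verify full rank."""
    kept, dropped = [], []
    for c in design.columns:
        xd = _difference(design[c].to_numpy(), orders.d, orders.D)
        scale = max(1.0, float(np.abs(design[c]).max()))
        (dropped if np.allclose(xd, 0.0, atol=1e-10 * scale) else kept).append(c)
    pruned = design[kept]
    Xd = np.column_stack([_difference(pruned[c].to_numpy(), orders.d, orders.D) for c in kept])
    _, r, piv = scipy.linalg.qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xd.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < len(kept):
        bad = [kept[j] for j in piv[rank:]]
        raise DesignError(f"collinear regressor columns after differencing: {bad}")
    return pruned, tuple(dropped)


# -- fitting -----------------------------------------------------------


def fit_its(
    y,
    X=None,
    orders: Orders | Sequence[int] = Orders(),
    include_trend: bool = True,
    outcome: str = "outcome",
) -> ITSFit:
    """Fit a SARIMA regression of ``y`` on [const, trend, X].

    ``y`` is the 60-month outcome vector (any length >= 24 is accepted),
    ``X`` a DataFrame of named intervention columns, ``orders`` the
    SARIMA orders.  With all orders zero the model is an ordinary
    Gaussian regression and the maximum-likelihood solution is computed
    in closed form.
    """
    if not isinstance(orders, Orders):
        orders = Orders(*orders)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if not np.isfinite(y).all():
        raise FitError("outcome vector contains non-finite values")
    design = _as_design(X, n, include_trend)
    design, dropped = _prune_and_check(design, orders)

    if orders.is_plain_regression:
        return _fit_ols(y, design, orders, outcome, dropped)
    return _fit_sarimax(y, design, orders, outcome, dropped)


def _fit_ols(y, design, orders, outcome, dropped) -> ITSFit:
    Xm = design.to_numpy()
    n, k = Xm.shape
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    sigma2 = float(resid @ resid) / n  # MLE variance, matching the state-space convention
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) if sigma2 > 0 else np.inf
    coeffs = {
        name: CoefficientEstimate.from_estimate_se(float(b), float(s))
        for name, b, s in zip(design.columns, beta, se)
    }
    n_params = k + 1  # + sigma2
    cov = pd.DataFrame(xtx_inv * sigma2, index=design.columns, columns=design.columns)
    return ITSFit(
        outcome=outcome,
        orders=orders,
        coefficients=coeffs,
        loglik=float(llf),
        aicc=_aicc(float(llf), n_params, n),
        residuals=resid,
        nobs=n,
        dropped_columns=dropped,
        cov=cov,
    )


def _fit_sarimax(y, design, orders, outcome, dropped) -> ITSFit:
    from statsmodels.tsa.statespace.sarimax import SARIMAX

    ys = pd.Series(y, index=design.index, name=outcome)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            ys,
            exog=design,
            order=orders.order,
            seasonal_order=orders.seasonal_order,
            trend="n",
            enforce_stationarity=True,
            enforce_invertibility=True,
        )
        res = model.fit(disp=0, maxiter=200, cov_type="oim")
        if not _converged(res):
            # one retry from the first pass's parameters via a derivative-free step
            res = model.fit(
                disp=0,
                maxiter=2000,
                method="nm",
                start_params=np.asarray(res.params),
                cov_type="oim",
            )
    if not _converged(res):
        raise FitError(
            f"orders {orders}: optimizer did not converge "
            f"(retvals: {res.mle_retvals})"
        )
    params = res.params
    bse = res.bse
    coeffs: dict[str, CoefficientEstimate] = {}
    for name in list(design.columns) + [p for p in params.index if p not in design.columns]:
        est, s = float(params[name]), float(bse[name])
        if not np.isfinite(s):
            s = np.nan
        coeffs[name] = CoefficientEstimate.from_estimate_se(est, s)
    burn = orders.d + SEASONAL_PERIOD * orders.D
    resid = np.asarray(res.resid, dtype=float)[burn:]
    n_eff = ys.size - burn
    n_params = params.size
    exog_names = list(design.columns)
    cov = res.cov_params().loc[exog_names, exog_names]
    return ITSFit(
        outcome=outcome,
        orders=orders,
        coefficients=coeffs,
        loglik=float(res.llf),
        aicc=_aicc(float(res.llf), n_params, n_eff),
        residuals=resid,
        nobs=ys.size,
        dropped_columns=dropped,
        cov=cov,
    )


def _converged(res) -> bool:
    rv = res.mle_retvals
    if rv.get("converged", True):
        return True
    # L-BFGS occasionally flags runs that start (and stay) at a stationary
    # point; accept when the gradient is numerically flat
    g = rv.get("gopt")
    return g is not None and np.isfinite(g).all() and float(np.abs(g).max()) < 1e-3


def _aicc(llf: float, k: int, n: int) -> float:
    if not np.isfinite(llf):
        return np.inf
    aic = -2.0 * llf + 2.0 * k
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


# -- order selection ---------------------------------------------------


def _kpss_pvalue(x: np.ndarray, regression: str) -> tuple[float, float, bool]:
    from statsmodels.tsa.stattools import kpss

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        stat, pvalue, *_ = kpss(x, regression=regression, nlags="auto")
    clamped = any("InterpolationWarning" in type(w.message).__name__ for w in caught)
    return float(stat), float(pvalue), clamped


def _seasonal_strength(x: np.ndarray) -> float:
    """F_s = max(0, 1 - Var(remainder)/Var(seasonal + remainder)) from STL."""
    from statsmodels.tsa.seasonal import STL

    res = STL(pd.Series(x), period=SEASONAL_PERIOD).fit()
    denom = np.var(res.seasonal + res.resid)
    if denom <= 0:
        return 0.0
    return max(0.0, 1.0 - np.var(res.resid) / denom)


def select_orders(
    y,
    X=None,
    include_trend: bool = True,
    max_p: int = 3,
    max_q: int = 3,
    max_P: int = 2,
    max_Q: int = 2,
    max_d: int = 2,
    d: int | None = None,
    D: int | None = None,
) -> Orders:
    """Choose SARIMA orders by a bounded stepwise AICc search.

    ``d`` (up to 2) is set by repeated KPSS level tests on the residuals
    of the deterministic regression [const, trend, X]; ``D`` in {0, 1}
    by the STL seasonal-strength heuristic (threshold 0.64).  Given
    (d, D), a stepwise hill-climb over (p, q, P, Q) minimizes AICc with
    the regressors included in every candidate fit.  Explicit ``d``/``D``
    override the heuristics.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    design = _as_design(X, n, include_trend)
    beta, *_ = np.linalg.lstsq(design.to_numpy(), y, rcond=None)
    resid0 = y - design.to_numpy() @ beta

    if d is None:
        d = 0
        x = resid0.copy()
        while d < max_d:
            _, p_kpss, _ = _kpss_pvalue(x, "c")
            if p_kpss >= ALPHA:
                break
            x = np.diff(x)
            d += 1
    if D is None:
        D = 1 if _seasonal_strength(resid0) > 0.64 else 0

    cache: dict[tuple[int, int, int, int], float] = {}
    attempted: list[str] = []

    def score(p: int, q: int, P: int, Q: int) -> float:
        key = (p, q, P, Q)
        if key in cache:
            return cache[key]
        orders = Orders(p, d, q, P, D, Q)
        attempted.append(str(orders))
        try:
            fit = fit_its(y, X, orders, include_trend=include_trend)
            val = fit.aicc
        except (FitError, DesignError, np.linalg.LinAlgError, ValueError):
            val = np.inf
        cache[key] = val
        return val

    starts = [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 0, 0)]
    if max_P or max_Q:
        starts += [(1, 0, 1, 0), (0, 0, 0, 1)]
    best = min(starts, key=lambda s: score(*s))
    if not np.isfinite(cache[best]):
        raise SelectionError(f"no candidate model converged; attempted: {attempted}")

    improved = True
    while improved:
        improved = False
        p, q, P, Q = best
        neighbors = []
        for dp, dq in ((1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)):
            neighbors.append((p + dp, q + dq, P, Q))
        for dP, dQ in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neighbors.append((p, q, P + dP, Q + dQ))
        for cand in neighbors:
            cp, cq, cP, cQ = cand
            if not (0 <= cp <= max_p and 0 <= cq <= max_q and 0 <= cP <= max_P and 0 <= cQ <= max_Q):
                continue
            if score(*cand) < cache[best] - 1e-9:
                best = cand
                improved = True
        # restart loop from the new best
    p, q, P, Q = best
    return Orders(p, d, q, P, D, Q)


# -- diagnostics -------------------------------------------------------


def diagnose(fit: ITSFit | np.ndarray, model_df: int = 0) -> DiagnosticsReport:
    """Ljung-Box (max lag 12) and KPSS level/trend tests on residuals.

    ``model_df`` optionally subtracts fitted ARMA parameters from the
    Ljung-Box degrees of freedom (default 0: the raw lag-12 test).
    Accepts an :class:`ITSFit` or a bare residual vector.
    """
    from statsmodels.stats.diagnostic import acorr_ljungbox

    resid = fit.residuals if isinstance(fit, ITSFit) else np.asarray(fit, dtype=float)
    if resid.size < SEASONAL_PERIOD + 1:
        raise InsufficientResidualsError(
            f"need at least {SEASONAL_PERIOD + 1} residuals, got {resid.size}"
        )
    lb = acorr_ljungbox(resid, lags=[SEASONAL_PERIOD], model_df=model_df)
    lb_stat = float(lb["lb_stat"].iloc[0])
    lb_p = float(lb["lb_pvalue"].iloc[0])
    lvl_stat, lvl_p, lvl_clamped = _kpss_pvalue(resid, "c")
    trd_stat, trd_p, trd_clamped = _kpss_pvalue(resid, "ct")
    return DiagnosticsReport(
        ljung_box_stat=lb_stat,
        ljung_box_pvalue=lb_p,
        ljung_box_pass=lb_p >= ALPHA,
        kpss_level_stat=lvl_stat,
        kpss_level_pvalue=lvl_p,
        kpss_level_pass=lvl_p >= ALPHA,
        kpss_trend_stat=trd_stat,
        kpss_trend_pvalue=trd_p,
        kpss_trend_pass=trd_p >= ALPHA,
        kpss_level_clamped=lvl_clamped,
        kpss_trend_clamped=trd_clamped,
    )
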