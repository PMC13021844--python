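import numpy as np
import pytest

import pharmits as ph
from pharmits.errors import DesignError, FitError, InsufficientResidualsError
from pharmits.its import Orders, diagnose, fit_its, select_orders
from pharmits.regressors import volume_design


def _ar1(rng, n=60, phi=0.5, sd=1.0):
    e = rng.standard_normal(n + 100) * sd
    x = np.zeros(n + 100)
    for k in range(1, n + 100):
        x[k] = phi * x[k - 1] + e[k]
    return x[100:]


class TestFit:
    def test_noiseless_ramp_recovered_exactly(self):
        X = volume_design()
        y = 10.0 + 0.2 * X["volume_ramp"].to_numpy()
        fit = fit_its(y, X, Orders())
        assert fit.coefficients["volume_ramp"].estimate == pytest.approx(0.2, abs=1e-6)
        assert fit.coefficients["const"].estimate == pytest.approx(10.0, abs=1e-6)
        assert fit.coefficients["volume_ramp"].pvalue < 1e-10

    def test_plain_regression_equals_closed_form_ols(self):
        """With zero orders the ML fit is ordinary least squares on [1, t, X]."""
        rng = np.random.default_rng(5)
        X = volume_design()
        y = 50 + 0.1 * np.arange(1, 61) + rng.standard_normal(60)
        fit = fit_its(y, X, Orders())
        design = np.column_stack(
            [np.ones(60), np.arange(1, 61), X.to_numpy()]
        )
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        got = [fit.coefficients[n].estimate for n in ("const", "trend", "volume_pulse", "volume_ramp")]
        assert np.allclose(got, beta, atol=1e-8)

    def test_ci_halfwidth_is_196_se(self):
        rng = np.random.default_rng(6)
        X = volume_design()
        y = 50 + 0.1 * np.arange(1, 61) + _ar1(rng)
        fit = fit_its(y, X, Orders(1, 0, 0))
        for c in fit.coefficients.values():
            if np.isfinite(c.se):
                assert c.ci_high - c.ci_low == pytest.approx(2 * 1.959963984540054 * c.se, rel=1e-9)
        assert "ar.L1" in fit.coefficients

    def test_differencing_drops_annihilated_columns(self):
        rng = np.random.default_rng(7)
        X = volume_design()
        y = np.cumsum(rng.standard_normal(60)) + 0.2 * X["volume_ramp"].to_numpy()
        fit = fit_its(y, X, Orders(0, 1, 0))
        assert "const" in fit.dropped_columns
        assert "volume_ramp" in fit.coefficients

    def test_collinear_columns_raise_design_error(self):
        X = volume_design()
        X = X.assign(ramp_copy=X["volume_ramp"])
        y = np.arange(60, dtype=float)
        with pytest.raises(DesignError, match="ramp_copy|volume_ramp"):
            fit_its(y, X, Orders())

    def test_nonfinite_outcome_rejected(self):
        y = np.full(60, np.nan)
        with pytest.raises(FitError):
            fit_its(y, volume_design(), Orders())

    def test_recovers_ramp_slope_on_average(self):
        """AR(1)-noise replicates: mean ramp estimate near the injected 0.2."""
        X = volume_design()
        ests = []
        for i in range(30):
            cfg = ph.SimulationConfig(
                regions=("r",),
                age_groups=("18-44",),
                sexes=("female",),
                seasonal_amplitude=0.0,
                ramp_slope=0.2,
                seed=200 + i,
            )
            s = next(iter(ph.simulate_volume_series(cfg).values()))
            y = ph.monthly_dddtid(s).to_numpy()
            fit = fit_its(y, X, Orders(1, 0, 0))
            ests.append(fit.coefficients["volume_ramp"].estimate)
        ests = np.asarray(ests)
        mcse = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - 0.2) < 4 * mcse


class TestSelectOrders:
    def test_fixed_orders_are_echoed(self):
        X = volume_design()
        y = 10 + 0.2 * X["volume_ramp"].to_numpy()
        fit = fit_its(y, X, Orders(0, 1, 1, 0, 0, 0))
        assert fit.orders == Orders(0, 1, 1, 0, 0, 0)

    def test_white_noise_needs_no_differencing(self):
        """On white noise the d/D heuristics choose no differencing and the
        stepwise search never does worse than the null model."""
        rng = np.random.default_rng(31)
        X = volume_design()
        null_like = 0
        for _ in range(8):
            y = 100 + rng.standard_normal(60)
            o = select_orders(y, X)
            assert (o.d, o.D) == (0, 0)
            null_like += o == Orders()
            aicc_sel = fit_its(y, X, o).aicc
            aicc_null = fit_its(y, X, Orders()).aicc
            assert aicc_sel <= aicc_null + 1e-9
        assert null_like >= 1  # the null order is reachable and chosen at times

    def test_seasonal_cycle_triggers_seasonal_terms(self):
        rng = np.random.default_rng(32)
        t = np.arange(1, 61)
        y = 100 + 0.1 * t + 5 * np.sin(2 * np.pi * t / 12) + 0.3 * rng.standard_normal(60)
        o = select_orders(y, volume_design())
        assert o.D == 1 or o.P > 0 or o.Q > 0


class TestDiagnose:
    def test_deterministic_in_residuals(self):
        rng = np.random.default_rng(8)
        resid = rng.standard_normal(60)
        assert diagnose(resid) == diagnose(resid.copy())

    def test_iid_residuals_pass(self):
        rng = np.random.default_rng(9)
        rep = diagnose(rng.standard_normal(60))
        assert rep.ljung_box_pass and rep.kpss_level_pass and rep.kpss_trend_pass

    def test_strong_ar1_residuals_fail_ljung_box(self):
        rng = np.random.default_rng(10)
        rep = diagnose(_ar1(rng, phi=0.9))
        assert not rep.ljung_box_pass

    def test_trending_residuals_fail_kpss_level(self):
        rng = np.random.default_rng(11)
        resid = np.linspace(0.0, 4.0, 60) + 0.3 * rng.standard_normal(60)
        rep = diagnose(resid)
        assert not rep.kpss_level_pass

    def test_short_residual_vector_rejected(self):
        with pytest.raises(InsufficientResidualsError):
            diagnose(np.zeros(12))

    def test_model_df_option_shrinks_ljung_box_dof(self):
        rng = np.random.default_rng(12)
        resid = rng.standard_normal(60)
        raw = diagnose(resid, model_df=0)
        adj = diagnose(resid, model_df=2)
        assert raw.ljung_box_stat == pytest.approx(adj.ljung_box_stat)
        assert adj.ljung_box_pvalue != raw.ljung_box_pvalue
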