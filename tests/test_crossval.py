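import numpy as np
import pytest

from rsrfit import (CurveSpec, RFConfig, SRSeries, fit_ls, fit_rsr,
                    generate_replicate, one_step_forecast, rf_error,
                    rf_from_sqerrors, select_phi, sr_log_mean,
                    ScenarioConfig)
from rsrfit.fitting import FitResult


def _manual_fit(curve, rho, eps_last, lam_last, method="RSR"):
    series = SRSeries([2000, 2001, 2002, 2003, 2004],
                      [100.0] * 5, [120.0] * 5)
    return FitResult(
        method=method, curve=curve, sigma=0.4, rho=rho, phi=1.0,
        eps=np.array([0.0, 0.0, 0.0, 0.0, eps_last]),
        lam=np.array([1.0, 1.0, 1.0, 1.0, lam_last]),
        loglik=0.0, converged=True, n_restarts_used=5, series=series,
    )


class TestOneStepForecast:
    def test_no_autocorrelation_gives_curve_mean(self):
        curve = CurveSpec("hs", 1.2, 500.0)
        fit = _manual_fit(curve, rho=0.0, eps_last=0.9, lam_last=0.5)
        assert one_step_forecast(fit, 800.0) == pytest.approx(
            sr_log_mean(800.0, curve))

    def test_full_weight_recovers_classic_ar1_forecast(self):
        curve = CurveSpec("hs", 1.2, 500.0)
        fit = _manual_fit(curve, rho=0.7, eps_last=0.4, lam_last=1.0)
        assert one_step_forecast(fit, 300.0) == pytest.approx(
            sr_log_mean(300.0, curve) + 0.7 * 0.4)

    def test_lad_carries_unweighted_residual(self):
        curve = CurveSpec("hs", 1.2, 500.0)
        fit = _manual_fit(curve, rho=0.7, eps_last=0.4, lam_last=0.25,
                          method="LAD")
        assert one_step_forecast(fit, 300.0) == pytest.approx(
            sr_log_mean(300.0, curve) + 0.7 * 0.4)

    def test_final_year_outlier_is_insulated(self, clean_replicate):
        # a gross outlier in the last training year barely moves the
        # forecast away from the curve mean
        series = clean_replicate.series
        r = series.r.copy()
        r[-1] += 3.5
        contaminated = SRSeries(series.year, series.S, np.exp(r))
        fit = fit_rsr(contaminated, phi=2.0)
        assert fit.lam[-1] < 0.01
        pred = one_step_forecast(fit, 600.0)
        f = sr_log_mean(600.0, fit.curve)
        assert abs(pred - f) < 0.05 * abs(fit.rho * fit.eps[-1]) + 1e-9


class TestRFScore:
    def test_constant_errors_give_squared_constant(self):
        for c in (0.3, 1.0, 2.5):
            assert rf_from_sqerrors(np.full(10, c**2)) == pytest.approx(c**2)

    def test_scales_quadratically(self):
        errs = np.array([0.2, 0.5, 1.1, 0.8])
        base = rf_from_sqerrors(errs**2)
        scaled = rf_from_sqerrors((3.0 * errs) ** 2)
        assert scaled == pytest.approx(9.0 * base)

    def test_single_fold_is_the_squared_error(self):
        assert rf_from_sqerrors([0.49]) == pytest.approx(0.49)

    def test_never_exceeds_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sq = rng.lognormal(size=rng.integers(2, 12)) ** 2
            assert rf_from_sqerrors(sq) <= sq.mean() * (1 + 1e-9)

    def test_zero_error_is_floored_not_fatal(self):
        val = rf_from_sqerrors([0.0, 1.0])
        assert np.isfinite(val) and val > 0


class TestRFError:
    def test_positive_and_deterministic(self, clean_replicate):
        cfg = RFConfig(P=5)
        v1 = rf_error(clean_replicate.series, "ls", cfg=cfg)
        v2 = rf_error(clean_replicate.series, "ls", cfg=cfg)
        assert v1 > 0
        assert v1 == v2

    def test_invariant_to_shifting_log_recruitment(self, clean_replicate):
        # adding a constant to r is absorbed by log(a) in the hockey-stick
        series = clean_replicate.series
        shifted = SRSeries(series.year, series.S, np.exp(series.r + 1.0))
        cfg = RFConfig(P=5)
        v = rf_error(series, "ls", cfg=cfg)
        vs = rf_error(shifted, "ls", cfg=cfg)
        assert vs == pytest.approx(v, rel=1e-2)

    def test_short_series_reduces_p_with_warning(self):
        cfg = ScenarioConfig(name="short", T=12, p=0.0, rho=0.0)
        series = generate_replicate(cfg, 4).series
        with pytest.warns(UserWarning, match="reduced to P=7"):
            rf_error(series, "ls", cfg=RFConfig(P=10))

    def test_unknown_method_rejected(self, clean_replicate):
        with pytest.raises(ValueError, match="method"):
            rf_error(clean_replicate.series, "huber")


class TestSelectPhi:
    def test_single_value_grid_returned(self, clean_replicate):
        cfg = RFConfig(P=3, phi_grid=[0.7])
        sel = select_phi(clean_replicate.series, cfg)
        assert sel.best_phi == 0.7
        assert list(sel.per_phi_error) == [0.7]

    def test_best_no_worse_than_smallest_phi(self):
        cfg = ScenarioConfig(name="contam", rho=0.8, p=0.2, q=1.0)
        series = generate_replicate(cfg, 99).series
        rf_cfg = RFConfig(P=5, phi_grid=np.exp([-3.0, -1.0, 1.0, 3.0]))
        sel = select_phi(series, rf_cfg)
        grid_min = float(np.exp(-3.0))
        assert sel.best_error <= sel.per_phi_error[grid_min] + 1e-12

    def test_reproducible(self, clean_replicate):
        cfg = RFConfig(P=4, phi_grid=np.exp([-3.0, 0.0]))
        s1 = select_phi(clean_replicate.series, cfg)
        s2 = select_phi(clean_replicate.series, cfg)
        assert s1.best_phi == s2.best_phi
        assert s1.per_phi_error == s2.per_phi_error

    def test_small_phi_fit_close_to_ls(self, clean_replicate):
        # at the smallest grid value the weights are ~1: RSR ~ LS
        series = clean_replicate.series
        rsr = fit_rsr(series, float(np.exp(-3.0)))
        ls = fit_ls(series)
        assert rsr.curve.a == pytest.approx(ls.curve.a, rel=0.1)
        assert rsr.curve.b == pytest.approx(ls.curve.b, rel=0.1)


class TestRFConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            RFConfig(P=0)
        with pytest.raises(ValueError):
            RFConfig(phi_grid=[])
        with pytest.raises(ValueError):
            RFConfig(phi_grid=[1.0, 0.5])
        with pytest.raises(ValueError):
            RFConfig(phi_grid=[-1.0, 1.0])

    def test_default_grid_is_the_13_point_log_grid(self):
        grid = RFConfig().phi_grid
        np.testing.assert_allclose(np.log(grid),
                                   np.arange(-3.0, 3.01, 0.5), atol=1e-12)
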