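import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import norm

from rsrfit import (CurveSpec, RSRParams, SRSeries, likelihood_terms,
                    log_likelihood, sr_log_mean, weights)
from rsrfit._kernels import _RIDGE, gauss_nll
from rsrfit.curves import FAMILY_CODES


def ar1_loglik_oracle(eps, sigma, rho):
    """Plain Gaussian AR(1) log-likelihood with stationary start.

    Written directly from the textbook factorization
    N(eps_1 | 0, sigma^2/(1-rho^2)) * prod N(eps_t | rho*eps_{t-1}, sigma^2);
    independent of the package's weighted-likelihood code path.
    """
    ll = norm.logpdf(eps[0], 0.0, sigma / np.sqrt(1.0 - rho**2))
    for t in range(1, len(eps)):
        ll += norm.logpdf(eps[t], rho * eps[t - 1], sigma)
    return ll


def random_instance(rng, T=None):
    T = T or rng.integers(5, 15)
    curve = CurveSpec("hs", rng.uniform(0.5, 3.0), rng.uniform(100, 800))
    S = rng.uniform(50, 1500, T)
    r = sr_log_mean(S, curve) + rng.normal(0, 0.5, T)
    series = SRSeries(np.arange(2000, 2000 + T), S, np.exp(r))
    params = RSRParams(curve, sigma=rng.uniform(0.1, 1.0),
                       rho=rng.uniform(0.0, 0.95), phi=0.0)
    return series, params


class TestWeights:
    @pytest.mark.parametrize("eps,phi,expected", [
        (0.0, 3.7, 1.0),          # zero residual -> full weight
        (2.5, 0.0, 1.0),          # phi=0 is the plain AR(1) special case
        (1.0, 1.0, np.exp(-1.0)),
    ])
    def test_known_values(self, eps, phi, expected):
        assert weights(np.array([eps]), phi)[0] == pytest.approx(expected)

    def test_negative_phi_rejected(self):
        with pytest.raises(ValueError):
            weights(np.zeros(3), -0.1)

    @given(
        # phi*eps^2 stays below ~700 so exp(-.) is representable (>0)
        eps=arrays(np.float64, st.integers(1, 20),
                   elements=st.floats(-5, 5)),
        phi=st.floats(0.0, 25.0),
    )
    def test_weights_in_unit_interval(self, eps, phi):
        lam = weights(eps, phi)
        assert np.all(lam > 0.0)
        assert np.all(lam <= 1.0)
        assert 0.0 < lam.mean() <= 1.0


class TestLikelihoodTerms:
    def test_iid_case_matches_plain_normal(self):
        # phi=0, rho=0: every year is an independent normal around the curve
        rng = np.random.default_rng(3)
        series, params = random_instance(rng, T=12)
        params = RSRParams(params.curve, params.sigma, rho=0.0, phi=0.0)
        terms = likelihood_terms(series, params)
        f = sr_log_mean(series.S, params.curve)
        expected = norm.logpdf(series.r, f, params.sigma)
        np.testing.assert_allclose(terms.per_year_loglik, expected, atol=1e-12)

    def test_single_year_uses_stationary_variance(self):
        series = SRSeries([2000], [300.0], [450.0])
        curve = CurveSpec("hs", 1.2, 500.0)
        params = RSRParams(curve, sigma=0.4, rho=0.6, phi=0.8)
        terms = likelihood_terms(series, params)
        eps = series.r[0] - sr_log_mean(300.0, curve)
        lam = np.exp(-0.8 * eps**2)
        var = 0.4**2 / (lam * (1.0 - 0.6**2 * lam))
        assert terms.lam_bar == pytest.approx(lam)
        assert terms.per_year_loglik[0] == pytest.approx(
            norm.logpdf(series.r[0], sr_log_mean(300.0, curve), np.sqrt(var))
        )

    def test_first_year_variance_formula(self):
        rng = np.random.default_rng(8)
        series, _ = random_instance(rng, T=10)
        params = RSRParams(CurveSpec("hs", 1.1, 400.0), 0.35, 0.7, 1.3)
        terms = likelihood_terms(series, params)
        expected_nu1 = 1.0 / (1.0 - 0.7**2 * terms.lam_bar)
        assert terms.nu[0] == pytest.approx(expected_nu1)
        assert np.all(terms.nu[1:] == 1.0)
        assert terms.delta[0] == 0.0

    def test_outlier_shrinks_carryover(self):
        # a gross residual at t-1 down-weights its carry into year t's mean
        curve = CurveSpec("hs", 1.0, 400.0)
        S = np.full(6, 300.0)
        r_clean = sr_log_mean(S, curve) + 0.1
        r_out = r_clean.copy()
        r_out[2] += 3.0  # gross positive outlier in year 3
        params = RSRParams(curve, 0.4, rho=0.8, phi=1.0)
        t_clean = likelihood_terms(
            SRSeries(np.arange(6), S, np.exp(r_clean)), params)
        t_out = likelihood_terms(
            SRSeries(np.arange(6), S, np.exp(r_out)), params)
        eps_prev = t_out.eps[2]
        naive_carry = abs(0.8 * eps_prev)
        assert abs(t_out.delta[3]) < naive_carry
        # and the outlier year's own variance is inflated vs the clean fit
        assert t_out.lam[2] < t_clean.lam[2]

    def test_variance_monotone_in_residual_magnitude(self):
        curve = CurveSpec("hs", 1.0, 400.0)
        params = RSRParams(curve, 0.4, rho=0.0, phi=0.5)
        S = np.full(5, 300.0)
        base = sr_log_mean(S, curve)
        lams = []
        for bump in (0.5, 1.0, 2.0):
            r = base.copy()
            r[2] += bump
            terms = likelihood_terms(SRSeries(np.arange(5), S, np.exp(r)),
                                     params)
            lams.append(terms.lam[2])
        assert lams[0] > lams[1] > lams[2]  # variance sigma^2/lam increases


class TestLogLikelihood:
    def test_phi_zero_matches_ar1_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            series, params = random_instance(rng)
            eps = series.r - sr_log_mean(series.S, params.curve)
            expected = ar1_loglik_oracle(eps, params.sigma, params.rho)
            assert log_likelihood(series, params) == pytest.approx(
                expected, abs=1e-8)

    def test_permutation_invariant_only_without_autocorrelation(self):
        rng = np.random.default_rng(5)
        series, params = random_instance(rng, T=10)
        perm = rng.permutation(10)
        shuffled = SRSeries(series.year, series.S[perm], series.R[perm])
        p0 = RSRParams(params.curve, params.sigma, rho=0.0, phi=0.7)
        assert log_likelihood(series, p0) == pytest.approx(
            log_likelihood(shuffled, p0), abs=1e-10)
        p8 = RSRParams(params.curve, params.sigma, rho=0.8, phi=0.7)
        assert log_likelihood(series, p8) != pytest.approx(
            log_likelihood(shuffled, p8), abs=1e-6)

    def test_jitted_kernel_matches_public_likelihood(self):
        # the optimizer's kernel and the public numpy path must agree
        # (up to the kernel's tiny documented ridge term)
        rng = np.random.default_rng(11)
        for _ in range(10):
            series, params = random_instance(rng, T=9)
            phi = rng.uniform(0, 5)
            params = RSRParams(params.curve, params.sigma, params.rho, phi)
            lo = 0.5 * series.S.min()
            span = 1.5 * series.S.max() - lo
            frac = (params.curve.b - lo) / span
            x = np.array([
                np.log(params.curve.a),
                np.log(frac / (1 - frac)),
                np.log(params.sigma),
                np.arctanh(params.rho),
            ])
            nll = gauss_nll(x, series.S, series.r, phi, FAMILY_CODES["hs"],
                            lo, span, False)
            ridge = _RIDGE * np.sum(x**2)
            assert nll - ridge == pytest.approx(
                -log_likelihood(series, params), abs=1e-9)


class TestRSRParams:
    @pytest.mark.parametrize("kw", [
        dict(sigma=-0.1), dict(sigma=0.0), dict(rho=1.0), dict(rho=-0.2),
        dict(phi=-1.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        base = dict(curve=CurveSpec("hs", 1.0, 100.0), sigma=0.4, rho=0.5,
                    phi=0.0)
        base.update(kw)
        with pytest.raises(ValueError):
            RSRParams(**base)
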