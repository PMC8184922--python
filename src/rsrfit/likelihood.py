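"""The robust spawner-recruitment (RSR) likelihood.

The model takes log-recruitment ``r_t = log R_t`` to be a stock-
recruitment curve mean plus a *scaled* first-order autoregressive error:

    r_t = f(S_t | theta) + eps_t,
    sqrt(lam_t) * (eps_t - rho * sqrt(lam_{t-1}) * eps_{t-1}) = e_t,

with Gaussian innovations ``e_t ~ N(0, sigma^2)`` and per-year weights

    lam_t = exp(-phi * eps_t^2),

where ``eps_t`` is the deviance residual from the mean curve. A year
far from the curve receives a small weight, which (i) inflates its
conditional variance to ``sigma^2 / lam_t`` — so the likelihood tolerates
the outlier — and (ii) shrinks its carry-over into the next year's
conditional mean through the factor ``sqrt(lam_{t-1})`` — so a single
extreme year cannot wreck the autocorrelation estimate. ``sqrt(lam_t)``
can be read as the probability that year ``t`` is uncontaminated. With
``phi = 0`` every weight is one and the model collapses to the ordinary
Gaussian AR(1) regression.

The first year uses the stationary solution of the scaled AR recursion:
zero mean shift and variance ``sigma^2 / (lam_1 * (1 - rho^2 *
lam_tilde))`` where ``lam_tilde`` is the sample mean of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import CurveSpec, sr_log_mean
from .series import SRSeries

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class RSRParams:
    """Full parameter set of the RSR likelihood.

    ``sigma`` is the base innovation SD on the log-recruitment scale,
    ``rho`` the lag-1 autocorrelation (non-negative by convention — a
    negative estimate is clipped during fitting), and ``phi`` the
    outlier-adjustment parameter (0 recovers plain AR(1)).
    """

    curve: CurveSpec
    sigma: float
    rho: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if not (np.isfinite(self.phi) and self.phi >= 0):
            raise ValueError(f"phi must be non-negative, got {self.phi}")


@dataclass(frozen=True)
class LikelihoodTerms:
    """Per-year decomposition of the RSR log-likelihood.

    Fields follow the model definition: deviance residuals ``eps``,
    weights ``lam`` with mean ``lam_bar``, conditional mean shifts
    ``delta`` (zero in year one), initial-condition variance inflators
    ``nu`` (``1/(1 - rho^2*lam_bar)`` in year one, one afterwards) and
    the per-year Gaussian log-densities.
    """

    eps: np.ndarray
    lam: np.ndarray
    lam_bar: float
    delta: np.ndarray
    nu: np.ndarray
    per_year_loglik: np.ndarray


def weights(eps, phi: float) -> np.ndarray:
    """Per-year weights ``lam = exp(-phi * eps**2)``.

    Always in (0, 1] for finite residuals; identically one when
    ``phi = 0`` (the plain AR(1) special case).
    """
    if not (np.isfinite(phi) and phi >= 0):
        raise ValueError(f"phi must be non-negative, got {phi}")
    eps = np.asarray(eps, dtype=np.float64)
    return np.exp(-phi * eps**2)


def likelihood_terms(series: SRSeries, params: RSRParams) -> LikelihoodTerms:
    """Evaluate the per-year pieces of the RSR log-likelihood.

    The year-one variance uses the stationary solution
    ``sigma^2 / (lam_1 * (1 - rho^2 * lam_bar))``; later years are
    conditionally Gaussian with mean ``f(S_t|theta) + rho *
    sqrt(lam_{t-1}) * eps_{t-1}`` and variance ``sigma^2 / lam_t``.
    Log-variances are assembled as ``2*log(sigma) + phi*eps**2`` so that
    a year whose weight underflows still contributes a finite term.
    """
    T = series.T
    eps = series.r - sr_log_mean(series.S, params.curve)
    eps = np.atleast_1d(eps)
    lam = weights(eps, params.phi)
    lam_bar = float(lam.mean())
    denom = 1.0 - params.rho**2 * lam_bar
    # rho < 1 and lam_bar <= 1 guarantee denom > 0
    delta = np.zeros(T)
    if T > 1:
        delta[1:] = params.rho * np.sqrt(lam[:-1]) * eps[:-1]
    nu = np.ones(T)
    nu[0] = 1.0 / denom

    z = eps - delta
    log_var = 2.0 * np.log(params.sigma) + params.phi * eps**2
    log_var[0] -= np.log(denom)
    inv_var_z2 = z**2 * lam / params.sigma**2
    inv_var_z2[0] *= denom
    per_year = -0.5 * (_LOG_2PI + log_var + inv_var_z2)
    return LikelihoodTerms(
        eps=eps, lam=lam, lam_bar=lam_bar, delta=delta, nu=nu,
        per_year_loglik=per_year,
    )


def log_likelihood(series: SRSeries, params: RSRParams) -> float:
    """Total RSR log-likelihood: the sum of the per-year terms."""
    return float(likelihood_terms(series, params).per_year_loglik.sum())
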