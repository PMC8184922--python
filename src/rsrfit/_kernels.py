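"""Jitted negative log-likelihood kernels used by the optimizer.

These mirror the public functions in :mod:`rsrfit.likelihood` but are
written as tight scalar loops so that the many thousands of objective
evaluations performed during multi-start fitting and phi-selection stay
cheap. Variances are handled on the log scale throughout: the per-year
log-variance is ``2*log(sigma) + phi*eps**2`` (minus ``log`` of the
stationary denominator in year one), which never overflows even when a
gross outlier drives its weight ``lambda_t = exp(-phi*eps_t**2)`` to an
underflowing value.

Parameters live on unconstrained scales: ``x = [log a, u_b, log sigma,
z_rho]`` with ``b = b_lo + span/(1+exp(-u_b))`` (a logistic map keeping
the break point inside the observed biomass range) and ``rho =
tanh(z_rho)``. Invalid parameter combinations return a large penalty
instead of raising, so simplex search continues smoothly.
"""

import math

import numpy as np
from numba import njit

_PENALTY = 1e10
_LOG_2PI = math.log(2.0 * math.pi)
#: tiny ridge on the transformed parameters; likelihood surfaces here have
#: exactly flat directions (b beyond max S in the hockey-stick, saturated
#: tanh(rho)) along which a simplex would otherwise drift without
#: terminating. Orders of magnitude below any meaningful likelihood
#: difference; reported log-likelihoods are recomputed without it.
_RIDGE = 1e-6


@njit(cache=True)
def _ridge(x):
    tot = 0.0
    for i in range(x.shape[0]):
        tot += x[i] * x[i]
    return _RIDGE * tot


@njit(cache=True)
def _log_mean(fam, la, b, s):
    """f(S|theta) for family code 0=hs, 1=bh, 2=ricker."""
    if fam == 0:
        m = s if s < b else b
        return la + math.log(m)
    elif fam == 1:
        return la + math.log(s / (1.0 + s / b))
    else:
        return la + math.log(s) - s / b


@njit(cache=True)
def gauss_nll(x, S, r, phi, fam, b_lo, b_span, fix_rho):
    """Negative log-likelihood of the weighted Gaussian AR(1) model.

    With ``phi = 0`` this is the exact Gaussian AR(1) conditional
    likelihood with stationary initial variance; ``fix_rho`` pins the
    autocorrelation at zero (``x`` then has three elements).
    """
    T = S.shape[0]
    la = x[0]
    b = b_lo + b_span / (1.0 + math.exp(-x[1]))
    two_ls = 2.0 * x[2]
    inv_sigma2 = math.exp(-two_ls)
    rho = 0.0 if fix_rho else math.tanh(x[3])
    if not (np.isfinite(b) and b > 0.0 and np.isfinite(inv_sigma2)):
        return _PENALTY

    eps = np.empty(T)
    lam = np.empty(T)
    lam_sum = 0.0
    for t in range(T):
        f = _log_mean(fam, la, b, S[t])
        e = r[t] - f
        if not np.isfinite(e):
            return _PENALTY
        eps[t] = e
        w = math.exp(-phi * e * e)
        lam[t] = w
        lam_sum += w
    lam_bar = lam_sum / T
    denom = 1.0 - rho * rho * lam_bar
    if denom <= 1e-12:
        return _PENALTY

    nll = 0.0
    for t in range(T):
        if t == 0:
            z = eps[0]
            log_var = two_ls + phi * eps[0] * eps[0] - math.log(denom)
            zsq_over_var = z * z * lam[0] * denom * inv_sigma2
        else:
            shift = rho * math.sqrt(lam[t - 1]) * eps[t - 1]
            z = eps[t] - shift
            log_var = two_ls + phi * eps[t] * eps[t]
            zsq_over_var = z * z * lam[t] * inv_sigma2
        nll += 0.5 * (_LOG_2PI + log_var + zsq_over_var)
    if not np.isfinite(nll):
        return _PENALTY
    return nll + _ridge(x)


@njit(cache=True)
def laplace_nll(x, S, r, fam, b_lo, b_span, fix_rho):
    """Negative log-likelihood of the Laplace AR(1) comparator (LAD).

    Conditional mean ``f(S_t|theta) + rho*eps_{t-1}`` (no weighting) and
    a common Laplace scale; maximizing it generalizes least absolute
    deviations to lag-1 autocorrelated residuals.
    """
    T = S.shape[0]
    la = x[0]
    b = b_lo + b_span / (1.0 + math.exp(-x[1]))
    scale = math.exp(x[2])
    rho = 0.0 if fix_rho else math.tanh(x[3])
    if not (np.isfinite(b) and b > 0.0 and np.isfinite(scale) and scale > 0.0):
        return _PENALTY

    nll = 0.0
    prev_eps = 0.0
    for t in range(T):
        f = _log_mean(fam, la, b, S[t])
        e = r[t] - f
        if not np.isfinite(e):
            return _PENALTY
        shift = rho * prev_eps if t > 0 else 0.0
        nll += math.log(2.0 * scale) + abs(e - shift) / scale
        prev_eps = e
    if not np.isfinite(nll):
        return _PENALTY
    return nll + _ridge(x)
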