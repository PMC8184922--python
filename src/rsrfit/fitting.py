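"""Maximum-likelihood fitting of the RSR model and its comparators.

Three estimators share one optimization engine:

``fit_rsr``
    Weighted Gaussian AR(1) maximum likelihood at a fixed value of the
    outlier-adjustment parameter phi (phi itself is chosen by
    retrospective forecasting, see :mod:`rsrfit.crossval`).
``fit_ls``
    The conventional least-squares comparator, implemented as Gaussian
    AR(1) maximum likelihood — exactly ``fit_rsr`` with phi pinned at 0.
``fit_lad``
    The least-absolute-deviations comparator, implemented as Laplace
    AR(1) maximum likelihood (conditional mean ``f + rho*eps_{t-1}``,
    common scale).

All methods optimize on unconstrained transformed scales (log a, a
logistic map of b into [0.5*min(S), 1.5*max(S)], log sigma, atanh rho)
with Nelder-Mead: the hockey-stick kink makes the surface multimodal,
and derivative-free search tolerates the non-differentiability at
S = b. A non-positive autocorrelation estimate is clipped to zero and
the remaining parameters re-optimized with rho fixed, returning a
coherent boundary maximum (negative lag-1 autocorrelation in
recruitment residuals is biologically implausible).

The RSR estimate at phi > 0 is defined by *continuation in phi*: the
Gaussian AR(1) fit at phi = 0 (located by a moment-based multi-start
search, where the likelihood is well behaved) anchors a chain of
warm-started local fits stepping up the phi grid. The weighted
likelihood at larger phi develops statistically degenerate distant
modes — rho near one with the curve pushed below the data and nearly
every weight collapsed, an effective random walk that treats most
years as contaminated. Continuation tracks the statistically
meaningful mode that grows out of the AR(1) solution instead of
hunting the global maximum into those pathologies, and is also much
cheaper when a whole phi grid is evaluated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._kernels import gauss_nll, laplace_nll
from .curves import FAMILY_CODES, CurveSpec, sr_log_mean
from .likelihood import RSRParams, likelihood_terms
from .series import SRSeries

#: multiplicative perturbations (a, b, sigma) and rho start per restart
_START_TABLE = (
    (1.0, 1.0, 1.0, 0.0),
    (1.0, 1.0, 1.0, 0.5),
    (1.5, 0.7, 1.0, 0.5),
    (0.7, 1.3, 1.0, 0.0),
    (1.0, 1.0, 1.5, 0.8),
)

_NM_OPTIONS = {"xatol": 1e-5, "fatol": 1e-9, "maxiter": 4000, "maxfev": 4000}

MIN_YEARS = 5  # 4 free parameters need a handful of degrees of freedom

#: canonical phi ladder used for continuation (the log-phi grid
#: -3.0 ... 3.0 in steps of 0.5, the same grid swept during selection)
DEFAULT_PHI_LADDER = tuple(
    float(v) for v in np.exp(np.arange(-3.0, 3.0 + 1e-9, 0.5))
)


def phi_ladder(phi: float) -> list[float]:
    """Ascending continuation path from 0 up to (and including) ``phi``."""
    return [g for g in DEFAULT_PHI_LADDER if g < phi * (1.0 - 1e-12)] + [
        float(phi)
    ]


@dataclass(frozen=True)
class FitResult:
    """A fitted SR model.

    ``sigma`` is the Gaussian innovation SD for RSR/LS and the Laplace
    scale for LAD. ``phi`` is the fixed outlier-adjustment value used
    (0 for LS, NaN for LAD where it plays no role). ``eps`` are the
    deviance residuals from the fitted curve and ``lam`` the fitted
    weights (identically one for LS and LAD). ``loglik`` is the
    maximized log-likelihood of the method's own model.
    """

    method: str
    curve: CurveSpec
    sigma: float
    rho: float
    phi: float
    eps: np.ndarray
    lam: np.ndarray
    loglik: float
    converged: bool
    n_restarts_used: int
    series: SRSeries

    @property
    def params(self) -> RSRParams:
        phi = 0.0 if not np.isfinite(self.phi) else self.phi
        return RSRParams(self.curve, self.sigma, self.rho, phi)


def clip_rho(rho_raw: float) -> float:
    """Clip a raw autocorrelation estimate to the [0, 1) range.

    Negative lag-1 autocorrelation is treated as impractical for
    recruitment residuals, so any non-positive estimate maps to zero.
    """
    return max(0.0, float(rho_raw))


def _b_bounds(S: np.ndarray) -> tuple[float, float]:
    # keep the break point near the observed biomass range; far outside
    # it the likelihood is flat in b and the search wanders
    return 0.5 * float(S.min()), 1.5 * float(S.max())


def _u_from_b(b: float, lo: float, span: float) -> float:
    frac = np.clip((b - lo) / span, 1e-6, 1.0 - 1e-6)
    return float(np.log(frac / (1.0 - frac)))


def _moment_init(series: SRSeries, family: str) -> tuple[float, float, float]:
    a0 = float(np.median(series.R / series.S))
    b0 = float(np.median(series.S))
    f0 = sr_log_mean(series.S, CurveSpec(family, a0, b0))
    s0 = max(float(np.std(series.r - f0)), 0.05)
    return a0, b0, s0


def _starts(series: SRSeries, family: str, n_restarts: int) -> list[np.ndarray]:
    a0, b0, s0 = _moment_init(series, family)
    lo, hi = _b_bounds(series.S)
    span = hi - lo
    out = []
    for am, bm, sm, rho0 in _START_TABLE[:n_restarts]:
        out.append(np.array([
            np.log(a0 * am),
            _u_from_b(b0 * bm, lo, span),
            np.log(s0 * sm),
            np.arctanh(rho0),
        ]))
    return out


def _run_starts(fun, args, starts):
    best = None
    for x0 in starts:
        res = minimize(fun, x0, args=args, method="Nelder-Mead",
                       options=_NM_OPTIONS)
        if best is None or res.fun < best.fun:
            best = res
    return best


_RHO_CAP = 1.0 - 1e-6  # keep the fitted process strictly stationary


def _decode(x, lo: float, span: float, fix_rho: bool):
    a = float(np.exp(x[0]))
    b = lo + span / (1.0 + np.exp(-x[1]))
    scale = float(np.exp(x[2]))
    rho_raw = 0.0 if fix_rho else float(np.tanh(x[3]))
    return a, float(b), scale, min(rho_raw, _RHO_CAP)


def _clip_and_decode(series, family, kernel, extra_args, res, n_used):
    """Decode an optimum, applying the rho-clipping boundary refit."""
    fam = FAMILY_CODES[family.lower()]
    lo, hi = _b_bounds(series.S)
    span = hi - lo
    a, b, scale, rho_raw = _decode(res.x, lo, span, fix_rho=False)
    converged = bool(res.success)
    if rho_raw <= 0.0:
        # boundary refit: re-optimize (theta, scale) with rho fixed at 0
        args0 = extra_args + (fam, lo, span, True)
        restarts = [res.x[:3].copy(), _starts(series, family, 1)[0][:3]]
        res = _run_starts(kernel, args0, restarts)
        n_used += len(restarts)
        a, b, scale, _ = _decode(res.x, lo, span, fix_rho=True)
        rho = 0.0
        converged = bool(res.success)
    else:
        rho = clip_rho(rho_raw)
    if not converged:
        warnings.warn(
            f"optimizer did not converge for family={family!r}; "
            "result flagged non-converged",
            RuntimeWarning, stacklevel=4,
        )
    return CurveSpec(family, a, b), scale, rho, converged, n_used


def _fit_engine(series: SRSeries, family: str, kernel, extra_args: tuple,
                n_restarts: int):
    """Multi-start fit + rho clipping (LS, LAD, and the phi=0 anchor)."""
    if series.T < MIN_YEARS:
        raise ValueError(
            f"need at least {MIN_YEARS} years to fit, got {series.T}"
        )
    fam = FAMILY_CODES[family.lower()]
    lo, hi = _b_bounds(series.S)
    span = hi - lo
    args = extra_args + (fam, lo, span, False)
    starts = _starts(series, family, n_restarts)
    best = _run_starts(kernel, args, starts)
    return _clip_and_decode(series, family, kernel, extra_args, best,
                            len(starts))


def _gauss_chain(series: SRSeries, family: str, phis, n_restarts: int):
    """Raw optimizer results along an ascending phi continuation path."""
    if series.T < MIN_YEARS:
        raise ValueError(
            f"need at least {MIN_YEARS} years to fit, got {series.T}"
        )
    fam = FAMILY_CODES[family.lower()]
    lo, hi = _b_bounds(series.S)
    span = hi - lo
    S, r = series.S, series.r
    starts = _starts(series, family, n_restarts)
    anchor = _run_starts(gauss_nll, (S, r, 0.0, fam, lo, span, False), starts)
    out, x = {}, anchor.x
    for phi in phis:
        if phi == 0.0:
            out[0.0] = anchor
            continue
        res = minimize(gauss_nll, x,
                       args=(S, r, float(phi), fam, lo, span, False),
                       method="Nelder-Mead", options=_NM_OPTIONS)
        out[phi] = res
        x = res.x
    return out, len(starts)


def _materialize_rsr(series: SRSeries, family: str, phi: float, res,
                     n_used: int) -> FitResult:
    curve, sigma, rho, converged, n_used = _clip_and_decode(
        series, family, gauss_nll, (series.S, series.r, float(phi)),
        res, n_used,
    )
    terms = likelihood_terms(series, RSRParams(curve, sigma, rho, phi))
    return FitResult(
        method="RSR", curve=curve, sigma=sigma, rho=rho, phi=float(phi),
        eps=terms.eps, lam=terms.lam,
        loglik=float(terms.per_year_loglik.sum()), converged=converged,
        n_restarts_used=n_used, series=series,
    )


def fit_rsr_path(series: SRSeries, phis, curve_family: str = "hs",
                 n_restarts: int = 5) -> dict:
    """Fit the RSR model along an ascending grid of phi values.

    One continuation chain serves the whole grid, so sweeping the
    13-point selection grid costs one anchored multi-start plus one
    warm-started local fit per grid value. The fit returned for each
    phi depends only on the grid values below it, so a sweep and a
    direct :func:`fit_rsr` call agree wherever their paths coincide.
    """
    phis = [float(p) for p in phis]
    if any(not np.isfinite(p) or p < 0 for p in phis):
        raise ValueError("phi values must be non-negative")
    if any(b <= a for a, b in zip(phis, phis[1:])):
        raise ValueError("phi values must be strictly increasing")
    chain, n_used = _gauss_chain(series, curve_family, phis, n_restarts)
    return {phi: _materialize_rsr(series, curve_family, phi, chain[phi],
                                  n_used)
            for phi in phis}


def fit_rsr(series: SRSeries, phi: float, curve_family: str = "hs",
            n_restarts: int = 5) -> FitResult:
    """Fit the RSR model by maximum likelihood at a fixed ``phi``.

    The estimate is the continuation fit reached by stepping up the
    canonical phi ladder from the Gaussian AR(1) anchor; ``phi = 0``
    is the anchor itself (identical to :func:`fit_ls` up to the
    method label).
    """
    if not (np.isfinite(phi) and phi >= 0):
        raise ValueError(f"phi must be non-negative, got {phi}")
    if phi == 0.0:
        curve, sigma, rho, converged, n_used = _fit_engine(
            series, curve_family, gauss_nll,
            (series.S, series.r, 0.0), n_restarts,
        )
        terms = likelihood_terms(series, RSRParams(curve, sigma, rho, 0.0))
        return FitResult(
            method="RSR", curve=curve, sigma=sigma, rho=rho, phi=0.0,
            eps=terms.eps, lam=terms.lam,
            loglik=float(terms.per_year_loglik.sum()), converged=converged,
            n_restarts_used=n_used, series=series,
        )
    return fit_rsr_path(series, phi_ladder(phi), curve_family,
                        n_restarts)[float(phi)]


def fit_ls(series: SRSeries, curve_family: str = "hs",
           n_restarts: int = 5) -> FitResult:
    """Conventional comparator: Gaussian AR(1) ML (RSR with phi = 0)."""
    fit = fit_rsr(series, 0.0, curve_family, n_restarts)
    return FitResult(
        method="LS", curve=fit.curve, sigma=fit.sigma, rho=fit.rho, phi=0.0,
        eps=fit.eps, lam=fit.lam, loglik=fit.loglik, converged=fit.converged,
        n_restarts_used=fit.n_restarts_used, series=series,
    )


def fit_lad(series: SRSeries, curve_family: str = "hs",
            n_restarts: int = 5) -> FitResult:
    """Robust comparator: Laplace AR(1) maximum likelihood (LAD).

    The conditional mean is ``f(S_t|theta) + rho*eps_{t-1}`` with a
    common Laplace scale — least absolute deviations generalized to
    autocorrelated residuals, with no outlier weighting.
    """
    curve, scale, rho, converged, n_used = _fit_engine(
        series, curve_family, laplace_nll,
        (series.S, series.r), n_restarts,
    )
    eps = np.atleast_1d(series.r - sr_log_mean(series.S, curve))
    shift = np.zeros(series.T)
    shift[1:] = rho * eps[:-1]
    loglik = float(np.sum(-np.log(2.0 * scale) - np.abs(eps - shift) / scale))
    return FitResult(
        method="LAD", curve=curve, sigma=scale, rho=rho, phi=float("nan"),
        eps=eps, lam=np.ones(series.T), loglik=loglik, converged=converged,
        n_restarts_used=n_used, series=series,
    )
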