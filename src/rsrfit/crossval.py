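"""Retrospective forecasting: time-series cross-validation for phi.

The outlier-adjustment parameter phi is not estimated jointly with the
likelihood (the weights depend on it circularly); instead it is chosen
by one-step-ahead forecast skill. Terminal years are deleted one at a
time on a rolling basis: for fold ``t`` the model is fitted to years
``1..T-t`` and the held-out year ``T-(t-1)`` is forecast with

    r_hat = f(S | theta_hat) + rho_hat * sqrt(lam_hat_last) * eps_hat_last,

where "last" is the final training year. The score is the geometric
mean of the squared log-scale forecast errors,

    RF_R = exp( (1/P) * sum_t log( (r_obs - r_hat)^2 ) ),

which is far less dominated by a single bad fold than the arithmetic
mean. phi is swept over a fixed grid (default exp(-3.0 .. 3.0) in steps
of 0.5 on the log scale, 13 values) and the minimizer selected, ties
going to the smallest phi (the value closest to plain AR(1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .curves import sr_log_mean
from .fitting import (DEFAULT_PHI_LADDER, MIN_YEARS, FitResult, fit_lad,
                      fit_ls, fit_rsr_path, phi_ladder)
from .series import SRSeries

#: floor applied to a squared fold error before taking logs (Eq. is
#: undefined at an exactly zero error, a measure-zero event on real data)
SQERR_FLOOR = 1e-12


def default_phi_grid() -> np.ndarray:
    """The log-phi grid -3.0 ... 3.0 in increments of 0.5."""
    return np.asarray(DEFAULT_PHI_LADDER)


@dataclass(frozen=True)
class RFConfig:
    """Retrospective-forecasting settings.

    ``P`` is the number of held-out terminal years (default 10; reduced
    automatically, with a warning, down to a minimum of 5 when the
    series is too short to leave 5 training years per fold).
    """

    P: int = 10
    phi_grid: np.ndarray = field(default_factory=default_phi_grid)

    def __post_init__(self) -> None:
        grid = np.asarray(self.phi_grid, dtype=np.float64)
        if self.P < 1:
            raise ValueError(f"P must be >= 1, got {self.P}")
        if grid.size == 0 or np.any(grid <= 0):
            raise ValueError("phi_grid must be a nonempty grid of positive values")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("phi_grid must be strictly increasing")
        object.__setattr__(self, "phi_grid", grid)

    def effective_P(self, T: int) -> int:
        if T - self.P < MIN_YEARS:
            p = T - MIN_YEARS
            if p < 1:
                raise ValueError(
                    f"series of length {T} is too short for retrospective "
                    f"forecasting (needs at least {MIN_YEARS + 1} years)"
                )
            warnings.warn(
                f"P={self.P} leaves fewer than {MIN_YEARS} training years; "
                f"reduced to P={p}",
                UserWarning, stacklevel=3,
            )
            return p
        return self.P


@dataclass(frozen=True)
class RFResult:
    """Outcome of a phi-grid sweep."""

    per_phi_error: dict
    best_phi: float
    fold_sqerr: dict
    n_folds: dict

    @property
    def best_error(self) -> float:
        return self.per_phi_error[self.best_phi]


def one_step_forecast(fit: FitResult, S_next: float) -> float:
    """One-step-ahead log-recruitment forecast from a fitted model.

    ``f(S_next|theta_hat) + rho_hat * sqrt(lam_last) * eps_last`` for
    RSR/LS (for LS every weight is one, recovering the classic AR(1)
    forecast); LAD uses the analogous term without the weight factor.
    A heavily down-weighted final training year therefore barely
    perturbs the forecast away from the curve mean.
    """
    if S_next <= 0:
        raise ValueError(f"S_next must be positive, got {S_next}")
    f = sr_log_mean(S_next, fit.curve)
    carry = 1.0 if fit.method == "LAD" else np.sqrt(fit.lam[-1])
    return float(f + fit.rho * carry * fit.eps[-1])


_METHODS = ("rsr", "ls", "lad")


def rf_from_sqerrors(sqerr) -> float:
    """Geometric mean of squared fold errors (the RF score)."""
    sqerr = np.maximum(np.asarray(sqerr, dtype=np.float64), SQERR_FLOOR)
    rf = float(np.exp(np.mean(np.log(sqerr))))
    # AM-GM: the geometric mean can never exceed the arithmetic mean
    assert rf <= float(np.mean(sqerr)) * (1.0 + 1e-9)
    return rf


def _fold_sqerrs(series: SRSeries, method: str, phis, P: int,
                 curve_family: str, n_restarts: int) -> dict:
    """Per-phi lists of squared one-step forecast errors over the folds.

    For RSR all candidate phi values in a fold share one continuation
    chain. Folds whose fit fails or does not converge are skipped with
    a warning (for the affected phi values only), never averaged as
    zeros.
    """
    T = series.T
    acc: dict = {phi: [] for phi in phis}
    for t in range(1, P + 1):
        train = series.truncated(T - t)
        try:
            if method == "rsr":
                fits = dict(fit_rsr_path(train, phis, curve_family,
                                         n_restarts))
            elif method == "ls":
                fits = {phis[0]: fit_ls(train, curve_family, n_restarts)}
            else:
                fits = {phis[0]: fit_lad(train, curve_family, n_restarts)}
        except ValueError as exc:
            warnings.warn(
                f"fold {t} (training years 1..{T - t}) failed: {exc}; "
                "fold skipped",
                UserWarning, stacklevel=4,
            )
            continue
        obs = float(series.r[T - t])
        S_next = float(series.S[T - t])
        for phi, fit in fits.items():
            if not fit.converged:
                warnings.warn(
                    f"fold {t} (training years 1..{T - t}) did not "
                    f"converge at phi={phi:g}; fold skipped",
                    UserWarning, stacklevel=4,
                )
                continue
            pred = one_step_forecast(fit, S_next)
            acc[phi].append(max((obs - pred) ** 2, SQERR_FLOOR))
    return acc


def rf_error(series: SRSeries, method: str = "rsr", phi: float = 0.0,
             cfg: RFConfig | None = None, curve_family: str = "hs",
             n_restarts: int = 5) -> float:
    """Retrospective-forecasting error RF_R of one method on one series.

    For ``method='rsr'`` the fixed ``phi`` is used in every fold fit;
    LS and LAD ignore it. Non-converged folds are skipped with a
    warning (effectively reducing P), never averaged in as zeros.
    """
    method = method.lower()
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}, got {method!r}")
    cfg = cfg or RFConfig()
    P = cfg.effective_P(series.T)
    phis = phi_ladder(phi) if method == "rsr" else [float(phi)]
    acc = _fold_sqerrs(series, method, phis, P, curve_family, n_restarts)
    sqerr = acc[phis[-1]]
    if not sqerr:
        raise RuntimeError("every retrospective-forecasting fold failed")
    return rf_from_sqerrors(sqerr)


def select_phi(series: SRSeries, cfg: RFConfig | None = None,
               curve_family: str = "hs", n_restarts: int = 5) -> RFResult:
    """Sweep the phi grid and pick the minimizer of RF_R.

    Every fold refits from scratch, so each candidate phi is judged by
    the full pipeline it would be used with. Ties break toward the
    smallest phi, the candidate closest to the plain AR(1) model.
    """
    cfg = cfg or RFConfig()
    P = cfg.effective_P(series.T)
    phis = [float(p) for p in cfg.phi_grid]
    acc = _fold_sqerrs(series, "rsr", phis, P, curve_family, n_restarts)
    per_phi, folds, n_folds = {}, {}, {}
    best_phi, best_err = None, np.inf
    for phi in phis:
        sqerr = np.asarray(acc[phi])
        if sqerr.size == 0:
            warnings.warn(f"phi={phi:g} failed in every fold", UserWarning,
                          stacklevel=2)
            continue
        err = rf_from_sqerrors(sqerr)
        per_phi[phi] = err
        folds[phi] = sqerr
        n_folds[phi] = int(sqerr.size)
        if err < best_err:  # strict: ties keep the earlier (smaller) phi
            best_phi, best_err = phi, err
    if best_phi is None:
        raise RuntimeError(
            f"phi selection failed for all {len(phis)} grid values"
        )
    return RFResult(per_phi_error=per_phi, best_phi=best_phi,
                    fold_sqerr=folds, n_folds=n_folds)
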