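"""Synthetic spawner-recruitment data with outliers and autocorrelation.

Each replicate draws spawning biomasses, a clean AR(1) log-residual
process, and sporadic gross outliers, then assembles observed
log-recruitment as

    r_t = f(S_t | theta) + omega_t + o_t,

where ``omega_1 ~ N(0, sigma^2/(1-rho^2))`` (stationary start) and
``omega_t = rho*omega_{t-1} + eta_t`` with ``eta_t ~ N(0, sigma^2)``.
Scenarios are calibrated by the *marginal* SD of the clean residual
(``resid_sd``, default 0.4 — typical log-recruitment variability for
fish stocks); the innovation SD is derived, ``sigma = resid_sd *
sqrt(1 - rho^2)``, so recruitment is equally variable whether or not
its residuals are autocorrelated. The contamination ``o_t`` is nonzero
with probability ``p`` per year, positive with probability ``q``, and
of gross magnitude ``2*resid_sd + |N(0, (2*resid_sd)^2)|`` — at least
two marginal noise SDs, i.e. genuinely extreme relative to the noise
floor, emulating sporadic exceptional cohorts or gross measurement
errors. Contamination is *added on top of* the clean AR process, which
continues undisturbed through outlier years; the next-year truth

    R_{T+1} = exp( f(S_{T+1}|theta) + rho*omega_T + eta_{T+1} )

therefore carries the clean autocorrelation signal and never an
outlier.

Spawning biomasses are iid lognormal with median b (log-SD 0.6),
truncated to [0.05*b, 4*b], so the observed range straddles the
hockey-stick break point and the curve is identifiable. Scenario S6
replaces the constant outlier probability with a spawner-dependent one
that decreases with the rank of S_t (poor spawning years are the ones
most prone to exceptional recruitment events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .curves import CurveSpec, sr_log_mean
from .series import SRSeries


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative truth for one simulation scenario."""

    name: str = "S0"
    family: str = "hs"
    a: float = 1.2
    b: float = 500.0
    resid_sd: float = 0.4  #: marginal SD of the clean log-scale residual
    rho: float = 0.8
    T: int = 30
    p: float = 0.2        #: per-year outlier probability
    q: float = 0.5        #: probability an outlier is positive
    start_year: int = 1991
    s_logsd: float = 0.6  #: log-SD of the lognormal spawner law
    s_lo_frac: float = 0.05
    s_hi_frac: float = 4.0
    spawner_dependent_p: bool = False
    p_min: float = 0.1
    p_max: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ValueError("p and q must lie in [0, 1]")
        if self.T < 10:
            raise ValueError(f"T must be >= 10, got {self.T}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")
        self.curve  # validates family/a/b via CurveSpec

    @property
    def curve(self) -> CurveSpec:
        return CurveSpec(self.family, self.a, self.b)

    @property
    def sigma(self) -> float:
        """AR(1) innovation SD implied by the marginal residual SD."""
        return self.resid_sd * np.sqrt(1.0 - self.rho**2)

    def outlier_probs(self, S: np.ndarray) -> np.ndarray:
        """Per-year outlier probability, constant or spawner-dependent."""
        T = len(S)
        if not self.spawner_dependent_p:
            return np.full(T, self.p)
        ranks = rankdata(S, method="ordinal")  # 1 = lowest spawning biomass
        return self.p_max - (self.p_max - self.p_min) * ranks / T

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["T"] = int(d["T"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)


@dataclass(frozen=True)
class SimReplicate:
    """One generated dataset plus the hidden truth behind it."""

    series: SRSeries
    omega: np.ndarray           #: clean AR(1) residuals
    outlier_flags: np.ndarray
    outlier_sizes: np.ndarray   #: signed contamination, 0 where no outlier
    S_next: float
    R_next_true: float
    eta_next: float
    config: ScenarioConfig


def _draw_spawners(rng: np.random.Generator, cfg: ScenarioConfig,
                   n: int) -> np.ndarray:
    lo, hi = cfg.s_lo_frac * cfg.b, cfg.s_hi_frac * cfg.b
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = cfg.b * np.exp(cfg.s_logsd * rng.standard_normal(n - filled))
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + len(keep)] = keep
        filled += len(keep)
    return out


def generate_replicate(cfg: ScenarioConfig, seed) -> SimReplicate:
    """Generate one replicate; byte-identical for identical seeds.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    T = cfg.T
    # draw order is fixed: spawners, AR innovations, flags, signs, sizes
    S_all = _draw_spawners(rng, cfg, T + 1)
    S, S_next = S_all[:T], float(S_all[T])

    z = rng.standard_normal(T + 1)
    omega = np.empty(T)
    omega[0] = cfg.sigma / np.sqrt(1.0 - cfg.rho**2) * z[0]
    for t in range(1, T):
        omega[t] = cfg.rho * omega[t - 1] + cfg.sigma * z[t]
    eta_next = float(cfg.sigma * z[T])

    flags = rng.random(T) < cfg.outlier_probs(S)
    signs = np.where(rng.random(T) < cfg.q, 1.0, -1.0)
    base = 2.0 * cfg.resid_sd  # two marginal noise SDs, the outlier floor
    gross = base + np.abs(rng.normal(0.0, base, T))
    sizes = np.where(flags, signs * gross, 0.0)

    f = sr_log_mean(S, cfg.curve)
    r = f + omega + sizes
    series = SRSeries(np.arange(cfg.start_year, cfg.start_year + T),
                      S, np.exp(r))
    R_next = float(np.exp(sr_log_mean(S_next, cfg.curve)
                          + cfg.rho * omega[-1] + eta_next))
    return SimReplicate(series=series, omega=omega, outlier_flags=flags,
                        outlier_sizes=sizes, S_next=S_next,
                        R_next_true=R_next, eta_next=eta_next, config=cfg)


#: contamination patterns of the base-case cells
_PATTERNS = {
    "none": dict(p=0.0, q=0.5),
    "balanced": dict(p=0.2, q=0.5),
    "positive": dict(p=0.2, q=1.0),
    "negative": dict(p=0.2, q=0.0),
}


def scenario_registry() -> dict:
    """Named scenario catalogue.

    ``S0`` is the base case (hockey-stick, a=1.2, b=500, T=30,
    rho=0.8, balanced outliers at p=0.2); ``S1``-``S6`` are its
    sensitivity variants (larger a; rarer/more frequent outliers;
    Beverton-Holt and Ricker truth; spawner-dependent outlier
    frequency). The eight ``S0_rho*_<pattern>`` entries are the
    base-case evaluation cells: rho in {0, 0.8} crossed with no
    outliers, balanced, all-positive and all-negative contamination.
    """
    s0 = ScenarioConfig(name="S0")
    reg = {
        "S0": s0,
        "S1": replace(s0, name="S1", a=1.8),
        "S2": replace(s0, name="S2", p=0.1),
        "S3": replace(s0, name="S3", p=0.3),
        "S4": replace(s0, name="S4", family="bh"),
        "S5": replace(s0, name="S5", family="ricker"),
        "S6": replace(s0, name="S6", spawner_dependent_p=True),
    }
    for rho in (0.0, 0.8):
        for pat, kv in _PATTERNS.items():
            name = f"S0_rho{rho:g}_{pat}"
            reg[name] = replace(s0, name=name, rho=rho, **kv)
    return reg


def get_scenario(name: str) -> ScenarioConfig:
    reg = scenario_registry()
    try:
        return reg[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; valid names: {sorted(reg)}"
        ) from None
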