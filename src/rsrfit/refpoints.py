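"""MSY reference points from a delay-difference equilibrium.

A fitted stock-recruitment curve is translated into management
quantities with a Deriso-Schnute delay-difference population model:
biomass next year is last year's survivors grown by a Ford coefficient
plus the incoming recruits,

    B_{t+1} = (1+g) * l * B_t - g * l^2 * B_{t-1} + w * R_{t+1},

where ``l = s * exp(-F)`` is total survival (natural survival ``s``
thinned by the fishing rate ``F``), ``g`` the Ford growth coefficient
and ``w`` the biomass of one recruit. At equilibrium this collapses to
a replacement line k(F) * B = R(B) with

    k(F) = (1 - (1+g)*l + g*l^2) / w,

whose intersection with the SR curve has a closed form for every
supported family. Yield is the harvested fraction of equilibrium
biomass, Y(F) = (1 - exp(-F)) * B*(F); F_msy maximizes Y over a fixed
grid and S_msy is the equilibrium spawning biomass there. When the
replacement slope k(F) exceeds the curve's slope at the origin the
equilibrium collapses to zero — fishing harder than F_msy on a
hockey-stick stock drops yield to nothing rather than tapering it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import CurveSpec


@dataclass(frozen=True)
class RefPointParams:
    """Delay-difference inputs for reference-point calculation.

    Defaults describe a moderately long-lived stock: natural survival
    0.7 per year, Ford growth coefficient 0.3, recruit weight 0.5 (in
    the biomass unit of the SR curve per recruit), fishing-rate grid
    0 to 2 per year in steps of 0.005.
    """

    survival: float = 0.7
    growth: float = 0.3
    recruit_weight: float = 0.5
    f_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 2.0 + 1e-9, 0.005)
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.survival < 1.0:
            raise ValueError(f"survival must lie in (0,1), got {self.survival}")
        if self.growth < 0.0:
            raise ValueError("growth coefficient must be non-negative")
        if self.recruit_weight <= 0.0:
            raise ValueError("recruit weight must be positive")
        grid = np.asarray(self.f_grid, dtype=np.float64)
        if grid.size < 2 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("f_grid must be increasing and non-negative")
        object.__setattr__(self, "f_grid", grid)


def replacement_slope(F, rp: RefPointParams):
    """k(F): recruits required per unit equilibrium biomass."""
    ell = rp.survival * np.exp(-np.asarray(F, dtype=np.float64))
    k = (1.0 - (1.0 + rp.growth) * ell + rp.growth * ell**2) / rp.recruit_weight
    return k


def equilibrium_biomass(curve: CurveSpec, F, rp: RefPointParams):
    """Equilibrium spawning biomass B*(F); zero when the stock collapses."""
    k = replacement_slope(F, rp)
    a, b = curve.a, curve.b
    with np.errstate(divide="ignore", invalid="ignore"):
        if curve.family == "hs":
            B = np.where(k < a, a * b / k, 0.0)
        elif curve.family == "bh":
            B = np.where(k < a, b * (a / k - 1.0), 0.0)
        else:  # ricker
            B = np.where(k < a, b * np.log(a / k), 0.0)
    return B if np.ndim(F) else float(B)


def equilibrium_yield(curve: CurveSpec, F, rp: RefPointParams):
    """Equilibrium yield Y(F) = (1 - exp(-F)) * B*(F)."""
    F = np.asarray(F, dtype=np.float64)
    Y = (1.0 - np.exp(-F)) * equilibrium_biomass(curve, F, rp)
    return Y if F.ndim else float(Y)


def msy_reference_points(curve: CurveSpec,
                         rp: RefPointParams | None = None
                         ) -> tuple[float, float]:
    """(F_msy, S_msy): fishing rate and spawning biomass at MSY.

    Evaluates equilibrium yield over the fishing-rate grid and returns
    the maximizer (first grid point on ties) and the equilibrium
    spawning biomass there.

    Raises ``ValueError`` when no grid point yields positive catch —
    i.e. the stock cannot replace itself under any fishing on the grid
    with these survival/growth parameters.
    """
    rp = rp or RefPointParams()
    Y = equilibrium_yield(curve, rp.f_grid, rp)
    assert np.all(np.isfinite(Y))
    i = int(np.argmax(Y))
    if Y[i] <= 0.0:
        raise ValueError(
            "no positive-yield equilibrium on the fishing-rate grid for "
            f"{curve} with survival={rp.survival}, growth={rp.growth}, "
            f"recruit_weight={rp.recruit_weight}"
        )
    F_msy = float(rp.f_grid[i])
    S_msy = float(equilibrium_biomass(curve, F_msy, rp))
    return F_msy, S_msy
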