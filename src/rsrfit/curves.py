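"""Stock-recruitment mean curves on the log scale.

Three classic curve families are supported, each parameterized by a
density-independent slope ``a`` and a density-dependence scale ``b``
(both positive, in the units of the series they are fitted to):

hockey-stick (``hs``)
    R = a * min(S, b): linear below the break point b, flat above.
Beverton-Holt (``bh``)
    R = a * S / (1 + S / b): saturating, asymptote R -> a*b as S -> inf.
Ricker (``ricker``)
    R = a * S * exp(-S / b): dome-shaped, peak a*b/e at S = b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("hs", "bh", "ricker")

#: integer codes used by the jitted likelihood kernels
FAMILY_CODES = {"hs": 0, "bh": 1, "ricker": 2}


@dataclass(frozen=True)
class CurveSpec:
    """A stock-recruitment curve family with its parameters theta = (a, b)."""

    family: str
    a: float
    b: float

    def __post_init__(self) -> None:
        fam = str(self.family).lower()
        if fam not in FAMILIES:
            raise ValueError(
                f"unknown curve family {self.family!r}; expected one of {FAMILIES}"
            )
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"curve parameter a must be positive, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ValueError(f"curve parameter b must be positive, got {self.b}")
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "b", float(self.b))


def sr_log_mean(S, curve: CurveSpec):
    """Log of the curve's mean recruitment at spawning biomass ``S``.

    Accepts a scalar or array of positive biomasses and returns the
    matching scalar or array of log-recruitment means f(S | theta).
    """
    S = np.asarray(S, dtype=np.float64)
    if np.any(S <= 0) or not np.all(np.isfinite(S)):
        raise ValueError("S must be finite and positive")
    if curve.family == "hs":
        out = np.log(curve.a * np.minimum(S, curve.b))
    elif curve.family == "bh":
        out = np.log(curve.a * S / (1.0 + S / curve.b))
    else:  # ricker
        out = np.log(curve.a * S) - S / curve.b
    return out if out.ndim else float(out)


def r0(curve: CurveSpec) -> float:
    """Asymptotic maximum recruitment R0 of a curve.

    For the hockey-stick this is the flat-part recruitment a*b; for
    Beverton-Holt the asymptote a*b; for Ricker the dome maximum a*b/e
    (attained at S = b).
    """
    if curve.family in ("hs", "bh"):
        return curve.a * curve.b
    return curve.a * curve.b / np.e
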