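"""Spawner-recruitment time series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SRSeries:
    """An observed spawner-recruitment time series.

    Parameters
    ----------
    year
        Strictly increasing, consecutive calendar years. Consecutiveness
        matters: the lag-1 autocorrelation term links each year to its
        immediate predecessor, so gaps would silently misalign residuals.
    S
        Spawning-stock biomass per year (any biomass unit, all positive).
    R
        Recruitment per year (any count or biomass unit, all positive).

    The log-recruitment vector ``r = log(R)`` is computed on construction
    and is the response variable of every model in this package.
    """

    year: np.ndarray
    S: np.ndarray
    R: np.ndarray
    r: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=np.int64)
        S = np.asarray(self.S, dtype=np.float64)
        R = np.asarray(self.R, dtype=np.float64)
        if not (year.ndim == S.ndim == R.ndim == 1):
            raise ValueError("year, S and R must be one-dimensional")
        if not (len(year) == len(S) == len(R)):
            raise ValueError(
                f"length mismatch: year={len(year)}, S={len(S)}, R={len(R)}"
            )
        if len(year) < 1:
            raise ValueError("series must contain at least one year")
        if np.any(np.diff(year) != 1):
            bad = int(np.flatnonzero(np.diff(year) != 1)[0])
            raise ValueError(
                f"years must be consecutive; gap between {year[bad]} and "
                f"{year[bad + 1]}"
            )
        if not np.all(np.isfinite(S)) or np.any(S <= 0):
            raise ValueError("spawner biomass S must be finite and positive")
        if not np.all(np.isfinite(R)) or np.any(R <= 0):
            raise ValueError("recruitment R must be finite and positive")
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "r", np.log(R))

    def __len__(self) -> int:
        return len(self.year)

    @property
    def T(self) -> int:
        """Number of observed years."""
        return len(self.year)

    def truncated(self, n: int) -> "SRSeries":
        """Return the series restricted to its first ``n`` years."""
        if not 1 <= n <= self.T:
            raise ValueError(f"n must be in [1, {self.T}], got {n}")
        return SRSeries(self.year[:n], self.S[:n], self.R[:n])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.year, "spawners": self.S, "recruits": self.R}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SRSeries":
        return cls(
            df["year"].to_numpy(),
            df["spawners"].to_numpy(),
            df["recruits"].to_numpy(),
        )
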