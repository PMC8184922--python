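"""Reading and writing spawner-recruitment tables and configs.

The canonical table is a comma-separated UTF-8 file with header columns
``year,spawners,recruits`` (and an optional ``population`` column for
multi-population files). Lines starting with ``#`` are comments and are
used to embed provenance (the resolved configuration and seed) in files
this package writes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .series import SRSeries
from .simulate import ScenarioConfig

REQUIRED_COLUMNS = ("year", "spawners", "recruits")


class SRTableError(ValueError):
    """Raised when a spawner-recruitment table fails validation."""


def _validate_group(df: pd.DataFrame, label: str) -> SRSeries:
    # row numbers reported as in the parsed table (1-based, post-comment)
    for col in ("spawners", "recruits"):
        bad = df.index[~(df[col] > 0) | ~df[col].notna()]
        if len(bad):
            raise SRTableError(
                f"{label}non-positive or missing {col!r} in table row "
                f"{bad[0] + 1}"
            )
    years = df["year"].to_numpy()
    gaps = (pd.Series(years).diff().dropna() != 1).to_numpy().nonzero()[0]
    if len(gaps):
        i = int(gaps[0])
        raise SRTableError(
            f"{label}years must be consecutive; gap after year {years[i]} "
            f"(table row {df.index[i] + 1})"
        )
    return SRSeries(years, df["spawners"].to_numpy(),
                    df["recruits"].to_numpy())


def read_sr_table(path, population=None):
    """Read a spawner-recruitment CSV.

    Returns a single ``SRSeries``; for multi-population files, the one
    named by ``population``, or a dict mapping population id to series
    when ``population`` is None.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SRTableError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    if "population" not in df.columns:
        return _validate_group(df.reset_index(drop=True), f"{path}: ")
    groups = {
        str(pop): _validate_group(g.reset_index(drop=True),
                                  f"{path} (population {pop!r}): ")
        for pop, g in df.groupby("population", sort=True)
    }
    if population is None:
        return groups
    try:
        return groups[str(population)]
    except KeyError:
        raise SRTableError(
            f"{path}: no population {population!r}; have {sorted(groups)}"
        ) from None


def write_sr_table(series: SRSeries, path, meta: dict | None = None) -> None:
    """Write a series as canonical CSV, embedding ``meta`` as # comments."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        series.to_frame().to_csv(fh, index=False)


def load_scenario_config(path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML key/value file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return ScenarioConfig.from_dict(data)


def save_scenario_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
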