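"""Readers/writers and run configuration.

Canonical interchange is a long-format CSV with one row per cell-year:
columns (year, cell, tair_anomaly, precip_index, co2_ppm, burned_frac,
harvest_frac). The monthly burn climatology travels in a sidecar JSON
provenance record together with seeds and parameter overrides.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcing import Forcing

FORCING_COLUMNS = ("year", "cell", "tair_anomaly", "precip_index",
                   "co2_ppm", "burned_frac", "harvest_frac")


def write_forcing(forcing: Forcing, path: str | Path) -> None:
    """Write a Forcing to long-format CSV plus a .meta.json sidecar."""
    path = Path(path)
    n_years, n_cells = forcing.tair_anomaly.shape
    years = np.repeat(forcing.years, n_cells)
    cells = np.tile(np.arange(n_cells), n_years)
    df = pd.DataFrame({
        "year": years,
        "cell": cells,
        "tair_anomaly": forcing.tair_anomaly.ravel(),
        "precip_index": forcing.precip_index.ravel(),
        "co2_ppm": np.repeat(forcing.co2_ppm, n_cells),
        "burned_frac": forcing.burned_fraction.ravel(),
        "harvest_frac": forcing.harvest_fraction.ravel(),
    })
    df.to_csv(path, index=False)
    meta = {"name": forcing.name,
            "monthly_burn_climatology":
                forcing.monthly_burn_climatology.tolist()}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2))


def read_forcing(path: str | Path) -> Forcing:
    """Read and validate a long-format forcing CSV.

    Raises a named error on missing columns, NaN in required fields, or
    out-of-range disturbance fractions (validation is delegated to the
    Forcing invariants)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in FORCING_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"forcing file {path} is missing column "
                             f"{col!r}")
    if df[list(FORCING_COLUMNS)].isna().any().any():
        bad = [c for c in FORCING_COLUMNS if df[c].isna().any()]
        raise ValueError(f"forcing file {path} has NaN in columns {bad}")
    years = np.sort(df["year"].unique())
    cells = np.sort(df["cell"].unique())
    n_years, n_cells = len(years), len(cells)
    if len(df) != n_years * n_cells:
        raise ValueError("forcing table is not a complete year x cell grid")
    df = df.sort_values(["year", "cell"])

    def grid(col: str) -> np.ndarray:
        return df[col].to_numpy().reshape(n_years, n_cells)

    co2 = grid("co2_ppm")
    if not np.allclose(co2, co2[:, :1]):
        raise ValueError("co2_ppm must be identical across cells per year")

    meta_path = path.with_suffix(path.suffix + ".meta.json")
    clim = np.full(12, 1.0 / 12.0)
    name = path.stem
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        clim = np.asarray(meta.get("monthly_burn_climatology", clim))
        name = meta.get("name", name)
    return Forcing(years=years, tair_anomaly=grid("tair_anomaly"),
                   precip_index=grid("precip_index"), co2_ppm=co2[:, 0],
                   burned_fraction=grid("burned_frac"),
                   harvest_fraction=grid("harvest_frac"),
                   monthly_burn_climatology=clim, name=name)


KNOWN_CONFIG_KEYS = {
    "seed", "n_cells", "start_year", "end_year",
    "transient_climate_start", "pre_era_end", "burn_mean", "burn_sigma",
    "inferred_offset_mha", "vector_offset_mha", "harvest_mean",
    "harvest_sd", "max_tiles", "spinup_tol", "window", "trend_window",
    "smooth_window", "alpha", "cell_area_m2", "output_dir", "params",
}


@dataclass
class RunConfig:
    """Structured run configuration with explicit seeds.

    `params` holds PftParams field overrides; everything else configures
    the generators and protocols. Unknown keys are rejected by name."""

    seed: int = 0
    n_cells: int = 25
    start_year: int = 1750
    end_year: int = 2023
    transient_climate_start: int = 1900
    pre_era_end: int = 1918
    burn_mean: float = 0.005
    burn_sigma: float = 0.8
    inferred_offset_mha: float = 3.2
    vector_offset_mha: float = 0.7
    harvest_mean: float = 0.002
    harvest_sd: float = 0.0005
    max_tiles: int = 12
    spinup_tol: float = 1e-4
    window: tuple[int, int] = (2002, 2022)
    trend_window: int = 15
    smooth_window: int = 10
    alpha: float = 0.05
    cell_area_m2: float = 1.6e11
    output_dir: str = "results"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start_year <= self.transient_climate_start
                <= self.end_year):
            raise ValueError("era boundaries must be ordered: start <= "
                             "transient_climate_start <= end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - KNOWN_CONFIG_KEYS
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["window"] = list(self.window)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: RunConfig,
                     extra: dict | None = None) -> None:
    """Machine-readable provenance record: config hash, seeds, params."""
    record = {"config_hash": config.config_hash(),
              "config": config.to_dict()}
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, default=str))
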