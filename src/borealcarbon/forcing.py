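"""Forcing container: annual climate indices, CO2, and disturbance fractions.

One `Forcing` holds a single disturbance scenario for a multi-cell domain
(or a single site, n_cells = 1): per cell-year air-temperature anomaly
(degC) and precipitation index (unitless), a global annual CO2 series
(ppm), per cell-year burned and harvested area fractions, and a 12-month
burned-area climatology used only to disaggregate annual burns for
monthly reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Forcing:
    years: np.ndarray  # (n_years,) int calendar years, contiguous
    tair_anomaly: np.ndarray  # (n_years, n_cells) degC
    precip_index: np.ndarray  # (n_years, n_cells) unitless
    co2_ppm: np.ndarray  # (n_years,) ppm
    burned_fraction: np.ndarray  # (n_years, n_cells) in [0, 1]
    harvest_fraction: np.ndarray  # (n_years, n_cells) in [0, 1]
    monthly_burn_climatology: np.ndarray = field(
        default_factory=lambda: np.full(12, 1.0 / 12.0))
    name: str = "forcing"

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for attr in ("tair_anomaly", "precip_index", "co2_ppm",
                     "burned_fraction", "harvest_fraction",
                     "monthly_burn_climatology"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        n = len(self.years)
        if n == 0:
            raise ValueError("forcing must cover at least one year")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("forcing years must be contiguous")
        for attr in ("tair_anomaly", "precip_index",
                     "burned_fraction", "harvest_fraction"):
            arr = getattr(self, attr)
            if arr.ndim != 2 or arr.shape[0] != n:
                raise ValueError(f"{attr} must have shape (n_years, n_cells)")
            if np.isnan(arr).any():
                raise ValueError(f"{attr} contains NaN")
        if self.co2_ppm.shape != (n,):
            raise ValueError("co2_ppm must have shape (n_years,)")
        if np.isnan(self.co2_ppm).any() or np.any(self.co2_ppm <= 0):
            raise ValueError("co2_ppm must be positive and NaN-free")
        for attr in ("burned_fraction", "harvest_fraction"):
            arr = getattr(self, attr)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{attr} must lie in [0, 1]")
        if np.any(self.burned_fraction + self.harvest_fraction > 1 + 1e-12):
            raise ValueError(
                "burned_fraction + harvest_fraction exceeds 1 for some cell-year")
        w = self.monthly_burn_climatology
        if w.shape != (12,) or np.any(w < 0):
            raise ValueError("monthly_burn_climatology must be 12 weights >= 0")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("monthly_burn_climatology must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.tair_anomaly.shape[1]

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def index_of(self, year: int) -> int:
        if not self.start_year <= year <= self.end_year:
            raise KeyError(f"year {year} outside forcing span "
                           f"{self.start_year}-{self.end_year}")
        return int(year - self.start_year)

    def co2_at(self, year: int) -> float:
        return float(self.co2_ppm[self.index_of(year)])

    def without_disturbance(self) -> "Forcing":
        """Counterfactual copy: burned and harvested fractions zeroed."""
        return Forcing(
            years=self.years.copy(),
            tair_anomaly=self.tair_anomaly.copy(),
            precip_index=self.precip_index.copy(),
            co2_ppm=self.co2_ppm.copy(),
            burned_fraction=np.zeros_like(self.burned_fraction),
            harvest_fraction=np.zeros_like(self.harvest_fraction),
            monthly_burn_climatology=self.monthly_burn_climatology.copy(),
            name=self.name + "+nodist",
        )
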