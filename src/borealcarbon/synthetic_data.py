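"""Seeded generators for forcing, the four-member disturbance-scenario
ensemble, and pseudo flux-tower observations.

The generators emulate the statistical structure that the analysis
assumes rather than any real geography:

* climate — AR(1) interannual air-temperature anomalies with a linear
  warming trend switched on at a configured year, and a smooth monotone
  CO2 ramp (defaults 289 -> 420 ppm over 1900-2023, extended back to the
  preindustrial level before 1900);
* disturbance — per-cell annual burned fractions drawn from a clipped
  lognormal (burned area is strongly right-skewed) and harvested
  fractions from a clipped normal. Four scenarios form a 2x2 ensemble:
  pre-boundary-era assumption {mean, inferred(+offset)} x
  observation-era source {raster, vector(+offset)}, sharing noise
  realizations so that variants differ only by the configured additive
  offsets;
* observations — model truth plus iid Gaussian noise per variable.

All generators are pure functions of (spec, seed). National Mha offsets
are mapped to area fractions through the nominal domain area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .forcing import Forcing

#: nominal domain area (m^2) used to convert Mha offsets to fractions;
#: roughly the forested area of a large boreal nation (400 Mha)
DOMAIN_AREA_M2 = 4.0e12
M2_PER_MHA = 1.0e10

#: default monthly burned-area climatology: boreal fire season peaking
#: June-August (weights sum to 1)
DEFAULT_BURN_CLIMATOLOGY = np.array(
    [0.0, 0.0, 0.005, 0.02, 0.10, 0.22, 0.30, 0.22, 0.10, 0.025, 0.01, 0.0])


def mha_per_year_to_fraction(mha: float,
                             domain_area_m2: float = DOMAIN_AREA_M2) -> float:
    """Convert a national Mha yr^-1 disturbance rate to an area fraction."""
    return mha * M2_PER_MHA / domain_area_m2


@dataclass(frozen=True)
class ScenarioSpec:
    """Statistical description of the four-member disturbance ensemble."""

    start_year: int = 1750
    end_year: int = 2023
    n_cells: int = 25
    #: mean annual burned fraction per cell (~2 Mha yr^-1 nationally)
    burn_mean: float = 0.005
    #: lognormal shape parameter (sd of log burned fraction)
    burn_sigma: float = 0.8
    #: boundary before which scenarios differ ("no reliable records" era)
    pre_era_end: int = 1918
    #: additive burn-fraction offset of the "inferred" pre-era variants
    #: (analogue of 3.2 Mha yr^-1 nationally)
    inferred_offset: float = mha_per_year_to_fraction(3.2)
    #: additive offset of the "vector" observation-era variants
    #: (analogue of 0.7 Mha yr^-1 nationally)
    vector_offset: float = mha_per_year_to_fraction(0.7)
    harvest_mean: float = 0.002
    harvest_sd: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inferred_offset < 0 or self.vector_offset < 0:
            raise ValueError("scenario offsets must be >= 0")
        if not self.start_year < self.pre_era_end < self.end_year:
            raise ValueError("pre_era_end must fall inside the year span")


def gen_forcing(years: np.ndarray | range, n_cells: int, seed: int, *,
                warming_rate: float = 0.025,
                warming_start: int = 1950,
                ar1_phi: float = 0.5,
                ar1_sd: float = 0.6,
                co2_preindustrial: float = 277.0,
                co2_1900: float = 289.0,
                co2_end: float = 420.0,
                co2_ramp_end: int = 2023,
                co2_shape: float = 2.2,
                monthly_climatology: np.ndarray | None = None,
                name: str = "synthetic") -> Forcing:
    """Generate synthetic climate + CO2 forcing (no disturbance).

    Temperature anomalies are cell-wise AR(1) noise plus a shared linear
    warming of `warming_rate` degC yr^-1 beginning at `warming_start`.
    CO2 follows a smooth monotone power ramp from `co2_1900` at 1900 to
    `co2_end` at `co2_ramp_end`, and a linear approach from the
    preindustrial level before 1900. Deterministic per seed.
    """
    years = np.asarray(list(years), dtype=int)
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(years)

    # AR(1) anomalies, stationary initialization
    eps = rng.normal(0.0, ar1_sd, size=(n, n_cells))
    tair = np.zeros((n, n_cells))
    if ar1_sd > 0:
        stat_sd = ar1_sd / np.sqrt(1.0 - ar1_phi ** 2)
        tair[0] = rng.normal(0.0, stat_sd, size=n_cells)
    for t in range(1, n):
        tair[t] = ar1_phi * tair[t - 1] + eps[t]
    trend = warming_rate * np.clip(years - warming_start, 0, None)
    tair = tair + trend[:, None]

    precip = 1.0 + 0.1 * rng.standard_normal((n, n_cells))

    co2 = np.empty(n)
    pre = years < 1900
    ramp = ~pre
    span = max(co2_ramp_end - 1900, 1)
    frac = np.clip((years[ramp] - 1900) / span, 0.0, 1.0)
    co2[ramp] = co2_1900 + (co2_end - co2_1900) * frac ** co2_shape
    if pre.any():
        pre_span = max(1900 - years[0], 1)
        co2[pre] = co2_preindustrial + (co2_1900 - co2_preindustrial) * (
            (years[pre] - years[0]) / pre_span)

    clim = (DEFAULT_BURN_CLIMATOLOGY if monthly_climatology is None
            else np.asarray(monthly_climatology, dtype=float))
    clim = clim / clim.sum()

    zeros = np.zeros((n, n_cells))
    return Forcing(years=years, tair_anomaly=tair, precip_index=precip,
                   co2_ppm=co2, burned_fraction=zeros,
                   harvest_fraction=zeros.copy(),
                   monthly_burn_climatology=clim, name=name)


SCENARIO_NAMES = ("mean_raster", "mean_vector",
                  "inferred_raster", "inferred_vector")


def gen_scenarios(spec: ScenarioSpec,
                  base_forcing: Forcing | None = None) -> dict[str, Forcing]:
    """Generate the 2x2 disturbance-scenario ensemble.

    All four scenarios share one climate/CO2 realization and one pair of
    burn-noise fields (pre- and post-boundary), so members differ only by
    the additive offsets: "inferred" variants add `inferred_offset` to
    the pre-boundary era; "vector" variants add `vector_offset` to the
    observation era. Fractions are clipped to [0, 1 - harvest].
    """
    years = np.arange(spec.start_year, spec.end_year + 1)
    if base_forcing is None:
        base_forcing = gen_forcing(years, spec.n_cells, spec.seed)
    if (base_forcing.start_year != spec.start_year
            or base_forcing.end_year != spec.end_year
            or base_forcing.n_cells != spec.n_cells):
        raise ValueError("base_forcing does not match the scenario spec")

    rng = np.random.default_rng(spec.seed + 1)
    n = len(years)
    # lognormal parameterized so the mean equals burn_mean
    mu = np.log(spec.burn_mean) - 0.5 * spec.burn_sigma ** 2
    burn_base = rng.lognormal(mu, spec.burn_sigma, size=(n, spec.n_cells))
    harvest = np.clip(
        rng.normal(spec.harvest_mean, spec.harvest_sd,
                   size=(n, spec.n_cells)), 0.0, 1.0)

    pre_mask = (years < spec.pre_era_end)[:, None]
    obs_mask = ~pre_mask

    out: dict[str, Forcing] = {}
    for name in SCENARIO_NAMES:
        pre_off = spec.inferred_offset if name.startswith("inferred") else 0.0
        obs_off = spec.vector_offset if name.endswith("vector") else 0.0
        burn = burn_base + pre_off * pre_mask + obs_off * obs_mask
        burn = np.clip(burn, 0.0, 1.0)
        over = burn + harvest > 1.0
        if over.any():
            burn = np.minimum(burn, 1.0 - harvest)
        out[name] = Forcing(
            years=years.copy(),
            tair_anomaly=base_forcing.tair_anomaly.copy(),
            precip_index=base_forcing.precip_index.copy(),
            co2_ppm=base_forcing.co2_ppm.copy(),
            burned_fraction=burn,
            harvest_fraction=harvest.copy(),
            monthly_burn_climatology=(
                base_forcing.monthly_burn_climatology.copy()),
            name=name)
    return out


class TowerTruth(NamedTuple):
    """Model truth at one pseudo-site over its observation window."""

    site_id: str
    disturbance_year: int
    disturbance_type: str  # "fire" | "harvest"
    years: np.ndarray
    gpp: np.ndarray
    er: np.ndarray
    nep: np.ndarray
    agb: np.ndarray


DEFAULT_NOISE_SD = {"GPP": 0.10, "ER": 0.10, "NEP": 0.06, "AGB": 0.60}


def gen_tower_obs(truths: list[TowerTruth], seed: int,
                  noise_sd: dict[str, float] | None = None) -> pd.DataFrame:
    """Add iid Gaussian observation noise to model truth.

    Returns a long table (site_id, variable, year, observed) plus the
    site's disturbance metadata; deterministic per seed.
    """
    if noise_sd is None:
        noise_sd = DEFAULT_NOISE_SD
    for v in noise_sd.values():
        if v < 0:
            raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for t in truths:
        series = {"GPP": t.gpp, "ER": t.er, "NEP": t.nep, "AGB": t.agb}
        for var, vals in series.items():
            sd = noise_sd.get(var, 0.0)
            noise = rng.normal(0.0, sd, size=len(vals)) if sd > 0 \
                else np.zeros(len(vals))
            for yr, tru, obs in zip(t.years, vals, vals + noise):
                rows.append({"site_id": t.site_id, "variable": var,
                             "year": int(yr), "truth": float(tru),
                             "observed": float(obs),
                             "disturbance_year": t.disturbance_year,
                             "disturbance_type": t.disturbance_type})
    return pd.DataFrame(rows)
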