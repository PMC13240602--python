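"""Reduced-complexity annual carbon-pool model with spin-up and transient
run protocols.

The model tracks eight carbon compartments per age tile (see
:mod:`borealcarbon.pools`). Annual gross primary productivity is

    GPP = gpp_max * vcmax_scale * f_age(a) * f_climate(dT) * f_co2(c)

with an age-recovery factor f_age = 1 - exp(-a / tau_rec), a climate
factor exp(beta_gpp * dT) on the air-temperature anomaly, and an
empirically downregulated CO2 fertilization factor
f_co2 = 1 + gamma * ln(c / c0). Maintenance respiration is paid by each
live pool at Q10-scaled rates, growth respiration is a fixed fraction of
GPP, and the remaining assimilate is allocated to leaves, stem, and
roots. Turnover routes tissue to litter (green leaves via a
standing-dead brown-leaf stage), litter decays with partial humification
into soil, and soil decays; both heterotrophic terms carry the same Q10.
Wood products decay exponentially as a separate atmospheric source.

Flux sign conventions: positive NBP denotes a land sink;
NBP = NEP - fire CO2 - product emissions. Harvest removals are internal
transfers and reach the atmosphere only through product decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .disturbance import decay_products
from .forcing import Forcing
from .params import FirePartitionTable, HarvestParams, PftParams, \
    default_initial_pools
from .pools import FIELDS, CarbonPools
from .tiling import Tile, TileSet, merge_tiles, split_tiles

LEDGER_FIELDS = ("gpp", "npp", "ra", "rh", "er", "nep", "fire_co2",
                 "harvest_removal", "product_emission", "nbp")


def co2_response(c: float, c0: float, gamma: float) -> float:
    """CO2 fertilization factor with empirical downregulation.

    Returns 1 + gamma * ln(c / c0), clipped below at zero. gamma = 0
    switches fertilization off; at the reference concentration the factor
    is exactly 1.
    """
    if not c > 0 or not c0 > 0:
        raise ValueError("CO2 concentrations must be positive")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    return max(0.0, 1.0 + gamma * math.log(c / c0))


def age_factor(age: float, tau_rec: float) -> float:
    """Post-disturbance GPP recovery: 1 - exp(-age / tau_rec)."""
    return 1.0 - math.exp(-age / tau_rec)


class YearForcing(NamedTuple):
    """One year's climate slice for a single cell."""

    tair_anomaly: float  # degC
    co2_ppm: float


class YearFluxes(NamedTuple):
    """Per-tile fluxes for one year, kg C m^-2 yr^-1."""

    gpp: float
    npp: float
    ra: float
    rh: float
    er: float
    nep: float
    product_emission: float


#: default wood-product decay rates (short-lived, long-lived), yr^-1
DEFAULT_PRODUCT_RATES = (HarvestParams().decay_rate_short,
                         HarvestParams().decay_rate_long)


def step_year(pools: CarbonPools, age: int, params: PftParams,
              yf: YearForcing,
              product_rates: tuple[float, float] = DEFAULT_PRODUCT_RATES
              ) -> tuple[CarbonPools, int, YearFluxes]:
    """Advance one tile by one year (explicit annual step).

    Returns the updated pools, age + 1, and the year's fluxes. The update
    conserves carbon exactly: the change in total pool mass equals
    GPP - Ra - Rh - product emissions.
    """
    if math.isnan(yf.tair_anomaly) or math.isnan(yf.co2_ppm):
        raise ValueError("forcing slice contains NaN")
    dT = yf.tair_anomaly
    q10f = params.q10 ** (dT / 10.0)
    rs = params.respiration_scale

    gpp = (params.gpp_max * params.vcmax_scale
           * age_factor(age, params.tau_rec)
           * math.exp(params.beta_gpp * dT)
           * co2_response(yf.co2_ppm, params.c0_ppm, params.gamma))

    m_green = rs * params.resp_rate_green_leaf * q10f * pools.green_leaf
    m_stem = rs * params.resp_rate_stem * q10f * pools.stem
    m_root = rs * params.resp_rate_root * q10f * pools.root
    growth_resp = rs * params.growth_resp_frac * gpp
    ra = m_green + m_stem + m_root + growth_resp
    alloc_in = gpp - growth_resp  # >= 0 by construction

    turn_green = pools.green_leaf / params.tau_green_leaf
    turn_brown = pools.brown_leaf / params.tau_brown_leaf
    turn_stem = pools.stem / params.tau_stem
    turn_root = pools.root / params.tau_root

    litter_decay = params.k_litter * q10f * pools.litter
    to_soil = params.humification_frac * litter_decay
    soil_decay = params.k_soil * q10f * pools.soil
    rh = (litter_decay - to_soil) + soil_decay

    # product-pool decay shares the annual step
    hp_short, hp_long, product_emission = decay_products(
        pools.products_short, pools.products_long,
        rate_short=product_rates[0], rate_long=product_rates[1])

    new = CarbonPools(
        green_leaf=(pools.green_leaf - m_green - turn_green
                    + params.alloc_leaf * alloc_in),
        brown_leaf=pools.brown_leaf + turn_green - turn_brown,
        stem=(pools.stem - m_stem - turn_stem
              + params.alloc_stem * alloc_in),
        root=(pools.root - m_root - turn_root
              + params.alloc_root * alloc_in),
        litter=(pools.litter - litter_decay
                + turn_brown + turn_stem + turn_root),
        soil=pools.soil - soil_decay + to_soil,
        products_short=hp_short,
        products_long=hp_long,
    )
    for f in FIELDS:
        if getattr(new, f) < 0.0:
            raise RuntimeError(
                f"internal error: pool {f!r} went negative during step_year")

    er = ra + rh
    nep = gpp - er
    return new, age + 1, YearFluxes(gpp, gpp - ra, ra, rh, er, nep,
                                    product_emission)


@dataclass
class FluxLedger:
    """Per-year diagnostic fluxes, kg C m^-2 yr^-1 at cell scale.

    Identities (validated): er = ra + rh; nep = gpp - er;
    nbp = nep - fire_co2 - product_emission.
    """

    years: np.ndarray
    gpp: np.ndarray
    npp: np.ndarray
    ra: np.ndarray
    rh: np.ndarray
    er: np.ndarray
    nep: np.ndarray
    fire_co2: np.ndarray
    harvest_removal: np.ndarray
    product_emission: np.ndarray
    nbp: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for f in LEDGER_FIELDS:
            setattr(self, f, np.asarray(getattr(self, f), dtype=float))
            if getattr(self, f).shape != self.years.shape:
                raise ValueError(f"ledger field {f} has wrong shape")
        self.validate()

    def validate(self, rtol: float = 1e-12) -> None:
        scale = np.maximum(np.abs(self.gpp) + np.abs(self.er), 1e-30)
        if np.any(np.abs(self.er - (self.ra + self.rh)) > rtol * scale):
            raise ValueError("ledger identity er = ra + rh violated")
        if np.any(np.abs(self.nep - (self.gpp - self.er)) > rtol * scale):
            raise ValueError("ledger identity nep = gpp - er violated")
        resid = self.nbp - (self.nep - self.fire_co2 - self.product_emission)
        if np.any(np.abs(resid) > rtol * np.maximum(scale, 1.0)):
            raise ValueError(
                "ledger identity nbp = nep - fire_co2 - product_emission "
                "violated")

    def to_dataframe(self) -> pd.DataFrame:
        data = {"year": self.years}
        data.update({f: getattr(self, f) for f in LEDGER_FIELDS})
        return pd.DataFrame(data)

    def window_mean(self, start: int, end: int, field_name: str) -> float:
        """Mean of a flux over calendar years [start, end] inclusive."""
        mask = (self.years >= start) & (self.years <= end)
        if not mask.any():
            raise KeyError(f"window {start}-{end} outside ledger years")
        return float(getattr(self, field_name)[mask].mean())


@dataclass(frozen=True)
class RunProtocol:
    """Era structure of a simulation.

    Climate loops over the first `loop_years` of the forcing until
    `transient_climate_start`; CO2 is transient from `start_year` on
    (held at the spin-up value during spin-up only). The site protocol
    spins up at year 1700, the domain protocol at 1750; both become fully
    transient in 1900.
    """

    start_year: int = 1750
    end_year: int = 2023
    transient_climate_start: int = 1900
    loop_years: int = 25

    def __post_init__(self) -> None:
        if not (self.start_year <= self.transient_climate_start
                <= self.end_year):
            raise ValueError("protocol era boundaries must be ordered")
        if self.loop_years < 1:
            raise ValueError("loop_years must be >= 1")


SITE_PROTOCOL = RunProtocol(start_year=1700, end_year=2023,
                            transient_climate_start=1900)
DOMAIN_PROTOCOL = RunProtocol(start_year=1750, end_year=2023,
                              transient_climate_start=1900)


@dataclass
class SpinupState:
    pools: CarbonPools
    age: int
    cycles: int


def run_spinup(params: PftParams, forcing: Forcing, cell: int = 0,
               loop_years: int | None = None, tol: float = 1e-4,
               max_cycles: int = 400,
               co2_ref: float | None = None) -> SpinupState:
    """Iterate the looped-climate cycle until total carbon equilibrates.

    CO2 is held at `co2_ref` (default: the PFT reference concentration
    c0). Convergence: |change in total carbon| over one full forcing
    cycle < tol (kg C m^-2). Deterministic. Raises on non-convergence,
    naming the slowest pool.
    """
    if loop_years is None:
        loop_years = min(25, len(forcing.years))
    if loop_years > len(forcing.years):
        raise ValueError("forcing shorter than the requested loop")
    c0 = params.c0_ppm if co2_ref is None else co2_ref
    tair = forcing.tair_anomaly[:loop_years, cell]

    pools = default_initial_pools()
    age = 0
    for cycle in range(1, max_cycles + 1):
        before = pools.copy()
        for i in range(loop_years):
            pools, age, _ = step_year(
                pools, age, params, YearForcing(float(tair[i]), c0))
        delta = pools.total() - before.total()
        if abs(delta) < tol:
            return SpinupState(pools, age, cycle)
    per_pool = {f: abs(getattr(pools, f) - getattr(before, f))
                for f in FIELDS}
    slowest = max(per_pool, key=per_pool.get)
    raise RuntimeError(
        f"spin-up did not converge within {max_cycles} cycles; slowest "
        f"pool is {slowest!r} (|delta| = {per_pool[slowest]:.3e} per cycle)")


@dataclass
class TransientResult:
    """Per-year output of a transient cell run."""

    ledger: FluxLedger
    agb: np.ndarray  # kg C m^-2, end of year, area-weighted
    total_carbon: np.ndarray  # kg C m^-2 incl. products, end of year
    tile_count: np.ndarray
    mean_age: np.ndarray
    tiles: TileSet  # final state
    tile_history: pd.DataFrame | None = None

    def closure_residual(self) -> float:
        """Relative whole-run conservation residual:
        |C(end) - C(start) - sum(NBP)| / max(|C(end)|, 1)."""
        dc = self.total_carbon[-1] - self._c_start
        return abs(dc - self.ledger.nbp.sum()) / max(
            abs(self.total_carbon[-1]), 1.0)

    _c_start: float = 0.0


def run_transient(init_state: SpinupState, params: PftParams,
                  forcing: Forcing, protocol: RunProtocol, cell: int = 0,
                  *, fire_table: FirePartitionTable | None = None,
                  harvest_params: HarvestParams | None = None,
                  disturbance: bool = True,
                  disturbance_start_year: int | None = None,
                  climate_transient: bool = True,
                  co2_transient: bool = True,
                  max_tiles: int = 12,
                  draw: str = "proportional",
                  record_tiles: bool = False) -> TransientResult:
    """Run one cell from the spin-up state through the protocol years.

    Each year: the scenario's burned/harvested fractions split the tile
    set (fire/harvest operators applied to the disturbed area), every
    tile steps one year, and the tile count is capped by merging.
    Factorial switches: `disturbance` zeroes all disturbance,
    `disturbance_start_year` zeroes it before a boundary year,
    `climate_transient=False` keeps climate looping for the whole run,
    `co2_transient=False` holds CO2 at the reference concentration.
    """
    if fire_table is None:
        fire_table = FirePartitionTable()
    if harvest_params is None:
        harvest_params = HarvestParams()
    product_rates = (harvest_params.decay_rate_short,
                     harvest_params.decay_rate_long)
    if (forcing.start_year > protocol.start_year
            or forcing.end_year < protocol.end_year):
        raise ValueError(
            f"forcing years {forcing.start_year}-{forcing.end_year} do not "
            f"cover protocol years {protocol.start_year}-{protocol.end_year}")

    years = np.arange(protocol.start_year, protocol.end_year + 1)
    n = len(years)
    loop_idx0 = forcing.index_of(protocol.start_year)
    pft_class = params.leaf_habit

    tiles = TileSet([Tile(1.0, init_state.age, init_state.pools.copy())],
                    max_tiles=max_tiles)
    cols = {f: np.zeros(n) for f in LEDGER_FIELDS}
    agb = np.zeros(n)
    total_c = np.zeros(n)
    tile_count = np.zeros(n, dtype=int)
    mean_age = np.zeros(n)
    history: list[dict] | None = [] if record_tiles else None
    c_start = tiles.total_carbon()

    for k, year in enumerate(years):
        yi = forcing.index_of(int(year))
        if climate_transient and year >= protocol.transient_climate_start:
            tair = float(forcing.tair_anomaly[yi, cell])
        else:
            li = loop_idx0 + (int(year) - protocol.start_year) \
                % protocol.loop_years
            tair = float(forcing.tair_anomaly[li, cell])
        co2 = forcing.co2_at(int(year)) if co2_transient else params.c0_ppm

        bf = float(forcing.burned_fraction[yi, cell])
        hf = float(forcing.harvest_fraction[yi, cell])
        if not disturbance:
            bf = hf = 0.0
        elif (disturbance_start_year is not None
              and year < disturbance_start_year):
            bf = hf = 0.0

        tiles, dist_flux = split_tiles(tiles, bf, hf, pft_class,
                                       fire_table, harvest_params, draw=draw)

        gpp = npp = ra = rh = prod_em = 0.0
        new_tiles: list[Tile] = []
        for t in tiles.tiles:
            pools, age, fx = step_year(
                t.pools, t.age, params, YearForcing(tair, co2),
                product_rates=product_rates)
            w = t.area_fraction
            gpp += w * fx.gpp
            npp += w * fx.npp
            ra += w * fx.ra
            rh += w * fx.rh
            prod_em += w * fx.product_emission
            new_tiles.append(Tile(w, age, pools))
        tiles = merge_tiles(TileSet(new_tiles, max_tiles=max_tiles))

        er = ra + rh
        nep = gpp - er
        nbp = nep - dist_flux.fire_co2 - prod_em
        for name, val in (("gpp", gpp), ("npp", npp), ("ra", ra),
                          ("rh", rh), ("er", er), ("nep", nep),
                          ("fire_co2", dist_flux.fire_co2),
                          ("harvest_removal", dist_flux.harvest_removal),
                          ("product_emission", prod_em), ("nbp", nbp)):
            cols[name][k] = val
        wp = tiles.weighted_pools()
        agb[k] = wp.agb()
        total_c[k] = wp.total()
        tile_count[k] = len(tiles)
        mean_age[k] = tiles.mean_age()
        if history is not None:
            for j, t in enumerate(tiles.tiles):
                row = {"year": int(year), "tile_id": j,
                       "area": t.area_fraction, "age": t.age}
                row.update(t.pools.as_dict())
                history.append(row)

    ledger = FluxLedger(years=years, **cols)
    result = TransientResult(
        ledger=ledger, agb=agb, total_carbon=total_c,
        tile_count=tile_count, mean_age=mean_age, tiles=tiles,
        tile_history=pd.DataFrame(history) if history is not None else None)
    result._c_start = c_start
    return result


@dataclass
class DomainResult:
    """Stacked per-cell transient results for one model run."""

    name: str
    years: np.ndarray
    fluxes: dict[str, np.ndarray]  # field -> (n_years, n_cells)
    agb: np.ndarray
    total_carbon: np.ndarray
    pools_final: pd.DataFrame  # per-cell area-weighted pools at end year

    def cell_ledger(self, cell: int) -> FluxLedger:
        return FluxLedger(years=self.years,
                          **{f: self.fluxes[f][:, cell]
                             for f in LEDGER_FIELDS})

    def mean_flux(self, field_name: str) -> np.ndarray:
        """Unweighted across-cell mean series (equal nominal cell areas)."""
        return self.fluxes[field_name].mean(axis=1)


def run_domain(params: PftParams, forcing: Forcing,
               protocol: RunProtocol = DOMAIN_PROTOCOL, *,
               fire_table: FirePartitionTable | None = None,
               harvest_params: HarvestParams | None = None,
               disturbance: bool = True,
               disturbance_start_year: int | None = None,
               climate_transient: bool = True,
               co2_transient: bool = True,
               max_tiles: int = 12,
               spinup_tol: float = 1e-4,
               name: str = "run",
               spinup_cache: dict[int, SpinupState] | None = None
               ) -> DomainResult:
    """Spin up and run every cell of a forcing scenario.

    `spinup_cache` lets factorial variants that share climate reuse each
    cell's equilibrium state (spin-up never sees CO2 trends or
    disturbance, so the cached state is identical across variants).
    """
    n_years = protocol.end_year - protocol.start_year + 1
    years = np.arange(protocol.start_year, protocol.end_year + 1)
    fluxes = {f: np.zeros((n_years, forcing.n_cells))
              for f in LEDGER_FIELDS}
    agb = np.zeros((n_years, forcing.n_cells))
    total_c = np.zeros((n_years, forcing.n_cells))
    pool_rows = []
    for cell in range(forcing.n_cells):
        if spinup_cache is not None and cell in spinup_cache:
            state = spinup_cache[cell]
        else:
            state = run_spinup(params, forcing, cell,
                               loop_years=protocol.loop_years,
                               tol=spinup_tol)
            if spinup_cache is not None:
                spinup_cache[cell] = state
        res = run_transient(
            state, params, forcing, protocol, cell,
            fire_table=fire_table, harvest_params=harvest_params,
            disturbance=disturbance,
            disturbance_start_year=disturbance_start_year,
            climate_transient=climate_transient,
            co2_transient=co2_transient, max_tiles=max_tiles)
        for f in LEDGER_FIELDS:
            fluxes[f][:, cell] = getattr(res.ledger, f)
        agb[:, cell] = res.agb
        total_c[:, cell] = res.total_carbon
        row = {"cell": cell}
        row.update(res.tiles.weighted_pools().as_dict())
        pool_rows.append(row)
    return DomainResult(name=name, years=years, fluxes=fluxes, agb=agb,
                        total_carbon=total_c,
                        pools_final=pd.DataFrame(pool_rows))
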