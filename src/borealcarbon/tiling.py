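"""Dynamic age-class tiling of a grid cell.

A cell is represented as a set of tiles, each an age cohort with an area
fraction, years-since-disturbance, and its own carbon pools. Disturbance
splits area off the existing tiles into a new age-0 tile; the tile count
is capped (default 12) by merging the pair of tiles closest in age.
Annual burned fractions can be disaggregated to months with a fixed
climatology for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .disturbance import apply_harvest, partition_fire
from .params import FirePartitionTable, HarvestParams
from .pools import FIELDS, CarbonPools

AREA_TOL = 1e-12


@dataclass
class Tile:
    area_fraction: float
    age: int
    pools: CarbonPools

    def __post_init__(self) -> None:
        if not self.area_fraction > 0:
            raise ValueError("tile area_fraction must be > 0")
        if self.age < 0:
            raise ValueError("tile age must be >= 0")


@dataclass
class TileSet:
    tiles: list[Tile]
    max_tiles: int = 12

    def __post_init__(self) -> None:
        if self.max_tiles < 1:
            raise ValueError("max_tiles must be >= 1")
        self.validate_area()

    def validate_area(self) -> None:
        total = sum(t.area_fraction for t in self.tiles)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tile areas sum to {total}, expected 1")

    def __len__(self) -> int:
        return len(self.tiles)

    def total_carbon(self) -> float:
        """Area-weighted total carbon of the cell, kg C m^-2."""
        return sum(t.area_fraction * t.pools.total() for t in self.tiles)

    def weighted_pools(self) -> CarbonPools:
        out = CarbonPools()
        for t in self.tiles:
            for f in FIELDS:
                setattr(out, f, getattr(out, f)
                        + t.area_fraction * getattr(t.pools, f))
        return out

    def mean_age(self) -> float:
        return sum(t.area_fraction * t.age for t in self.tiles)

    def copy(self) -> "TileSet":
        return TileSet([Tile(t.area_fraction, t.age, t.pools.copy())
                        for t in self.tiles], self.max_tiles)


class SplitFluxes(NamedTuple):
    """Cell-level (per m^2 of cell) fluxes from the year's disturbance."""

    fire_co2: float
    harvest_removal: float
    fire_litter: float
    harvest_residue: float


def split_tiles(tiles: TileSet, burned_frac: float, harvest_frac: float,
                pft_class: str, fire_table: FirePartitionTable,
                harvest_params: HarvestParams,
                draw: str = "proportional") -> tuple[TileSet, SplitFluxes]:
    """Disturb a cell: carve the disturbed area out of existing tiles,
    run it through the fire/harvest operators, and pool it into one new
    age-0 tile. Area and carbon are conserved exactly (carbon up to the
    combusted CO2 flux, which is returned).

    `draw` selects which tiles supply the disturbed area: "proportional"
    (default; every tile loses the same fraction) or "oldest" (oldest
    tiles consumed first).
    """
    if burned_frac < 0 or harvest_frac < 0:
        raise ValueError("disturbance fractions must be >= 0")
    dist = burned_frac + harvest_frac
    if dist > 1.0 + AREA_TOL:
        raise ValueError(
            f"burned + harvested fraction {dist} exceeds available area")
    if dist <= 0.0:
        return tiles, SplitFluxes(0.0, 0.0, 0.0, 0.0)

    # area taken from each tile
    takes: list[float]
    if draw == "proportional":
        takes = [t.area_fraction * dist for t in tiles.tiles]
    elif draw == "oldest":
        takes = [0.0] * len(tiles)
        remaining = dist
        order = sorted(range(len(tiles)),
                       key=lambda i: -tiles.tiles[i].age)
        for i in order:
            take = min(tiles.tiles[i].area_fraction, remaining)
            takes[i] = take
            remaining -= take
            if remaining <= AREA_TOL:
                break
        if remaining > AREA_TOL:
            raise ValueError("disturbance demand exceeds available area")
    else:
        raise ValueError(f"unknown draw policy {draw!r}")

    burn_share = burned_frac / dist
    harv_share = harvest_frac / dist

    fire_co2 = 0.0
    fire_litter = 0.0
    harvest_removal = 0.0
    harvest_residue = 0.0
    new_pools = CarbonPools()
    new_area = 0.0
    survivors: list[Tile] = []

    for tile, take in zip(tiles.tiles, takes):
        if take > 0.0:
            burn_area = take * burn_share
            harv_area = take * harv_share
            if burn_area > 0.0:
                res = partition_fire(tile.pools, pft_class, fire_table)
                fire_co2 += burn_area * res.co2_mass
                fire_litter += burn_area * res.litter_gain
                for f in FIELDS:
                    setattr(new_pools, f, getattr(new_pools, f)
                            + burn_area * getattr(res.pools, f))
            if harv_area > 0.0:
                res = apply_harvest(tile.pools, harvest_params)
                harvest_removal += harv_area * res.product_transfer
                harvest_residue += harv_area * res.residue_litter
                for f in FIELDS:
                    setattr(new_pools, f, getattr(new_pools, f)
                            + harv_area * getattr(res.pools, f))
            new_area += take
        left = tile.area_fraction - take
        if left > 0.0:
            survivors.append(Tile(left, tile.age, tile.pools))

    # new tile pools are per m^2 of the new tile
    survivors.append(Tile(new_area, 0, new_pools.scaled(1.0 / new_area)))
    out = TileSet(survivors, tiles.max_tiles)
    return out, SplitFluxes(fire_co2, harvest_removal,
                            fire_litter, harvest_residue)


def merge_tiles(tiles: TileSet) -> TileSet:
    """Cap the tile count by merging nearest-age pairs.

    While the count exceeds max_tiles, the pair with the smallest age
    difference (ties broken by smallest combined area) is merged into one
    tile with summed area, area-weighted mean pools, and area-weighted
    mean age rounded to the nearest year. Conserves area and carbon.
    """
    if len(tiles) <= tiles.max_tiles:
        return tiles
    work = [Tile(t.area_fraction, t.age, t.pools.copy()) for t in tiles.tiles]
    while len(work) > tiles.max_tiles:
        work.sort(key=lambda t: t.age)
        best = None
        for i in range(len(work) - 1):
            a, b = work[i], work[i + 1]
            key = (abs(a.age - b.age), a.area_fraction + b.area_fraction)
            if best is None or key < best[0]:
                best = (key, i)
        i = best[1]
        a, b = work[i], work[i + 1]
        area = a.area_fraction + b.area_fraction
        wa, wb = a.area_fraction / area, b.area_fraction / area
        merged_pools = CarbonPools(
            *(wa * getattr(a.pools, f) + wb * getattr(b.pools, f)
              for f in FIELDS))
        merged_age = int(round(wa * a.age + wb * b.age))
        work[i:i + 2] = [Tile(area, merged_age, merged_pools)]
    return TileSet(work, tiles.max_tiles)


def disaggregate_burn(annual_frac: float,
                      monthly_weights: np.ndarray) -> np.ndarray:
    """Spread an annual burned fraction over 12 months by climatology.

    monthly[i] = annual * w[i] / sum(w); the monthly values sum to the
    annual fraction exactly (last month absorbs rounding). Reporting only.
    """
    w = np.asarray(monthly_weights, dtype=float)
    if w.shape != (12,):
        raise ValueError("monthly_weights must have length 12")
    if np.any(w < 0):
        raise ValueError("monthly_weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValueError("monthly_weights must not be all zero")
    monthly = annual_frac * w / total
    monthly[-1] += annual_frac - monthly.sum()  # exact closure
    return monthly
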