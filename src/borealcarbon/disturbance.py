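"""Stand-replacing fire and harvest operators, and wood-product decay.

Each operator acts on the pools of the disturbed area (per m^2 of that
area) and conserves carbon exactly: fire splits every tissue into a
combusted CO2 flux, a litter transfer, and a small retained live
residual; harvest moves stem wood into product pools and everything else
killed to litter, with no direct atmospheric flux; product pools decay to
the atmosphere as a first-order source.
"""

from __future__ import annotations

from typing import NamedTuple

from .params import FirePartitionTable, HarvestParams
from .pools import CarbonPools


class FireResult(NamedTuple):
    pools: CarbonPools  # surviving pools on the new age-0 tile
    co2_mass: float  # kg C m^-2 combusted to the atmosphere
    litter_gain: float  # kg C m^-2 transferred into litter


class HarvestResult(NamedTuple):
    pools: CarbonPools
    product_transfer: float  # kg C m^-2 moved into product pools
    residue_litter: float  # kg C m^-2 of logging residue to litter


def partition_fire(pools: CarbonPools, pft_class: str,
                   table: FirePartitionTable) -> FireResult:
    """Apply stand-replacing fire to the pools of a burned area.

    Live tissues follow the per-tissue combustion/litter split; litter and
    soil lose their combustion fractions; wood-product pools are untouched.
    Mass in = surviving mass + CO2 exactly.
    """
    gl = table.green_leaf(pft_class)
    st = table.stem(pft_class)
    bl = table.brown_leaf
    rt = table.root

    co2 = (pools.green_leaf * gl.frac_to_co2
           + pools.brown_leaf * bl.frac_to_co2
           + pools.stem * st.frac_to_co2
           + pools.root * rt.frac_to_co2
           + pools.litter * table.litter_combust_frac
           + pools.soil * table.soil_combust_frac)
    litter_gain = (pools.green_leaf * gl.frac_to_litter
                   + pools.brown_leaf * bl.frac_to_litter
                   + pools.stem * st.frac_to_litter
                   + pools.root * rt.frac_to_litter)
    survivors = CarbonPools(
        green_leaf=pools.green_leaf * gl.frac_retained,
        brown_leaf=pools.brown_leaf * bl.frac_retained,
        stem=pools.stem * st.frac_retained,
        root=pools.root * rt.frac_retained,
        litter=pools.litter * (1.0 - table.litter_combust_frac) + litter_gain,
        soil=pools.soil * (1.0 - table.soil_combust_frac),
        products_short=pools.products_short,
        products_long=pools.products_long,
    )
    return FireResult(survivors, co2, litter_gain)


def apply_harvest(pools: CarbonPools, params: HarvestParams) -> HarvestResult:
    """Clear-cut harvest of the pools of a harvested area.

    No direct atmospheric flux: emissions occur later through
    `decay_products`. Conservation is exact.
    """
    removed = pools.stem * params.stem_removed_frac
    residue = (pools.stem * (1.0 - params.stem_removed_frac)
               + pools.green_leaf + pools.brown_leaf + pools.root)
    survivors = CarbonPools(
        green_leaf=0.0,
        brown_leaf=0.0,
        stem=0.0,
        root=0.0,
        litter=pools.litter + residue,
        soil=pools.soil,
        products_short=pools.products_short + removed * params.product_short_frac,
        products_long=pools.products_long + removed * params.product_long_frac,
    )
    return HarvestResult(survivors, removed, residue)


def decay_products(products_short: float, products_long: float,
                   rate_short: float, rate_long: float,
                   dt: float = 1.0) -> tuple[float, float, float]:
    """First-order product-pool decay over one time step.

    Discretization is exact exponential: remaining = pool * exp(-rate*dt),
    so a rate of ln(2) halves the pool per year. Returns
    (products_short, products_long, emission).
    """
    import math

    if rate_short < 0 or rate_long < 0:
        raise ValueError("product decay rates must be >= 0")
    new_short = products_short * math.exp(-rate_short * dt)
    new_long = products_long * math.exp(-rate_long * dt)
    emission = (products_short - new_short) + (products_long - new_long)
    return new_short, new_long, emission
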