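"""Fire/harvest partitioning and wood-product decay operators."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealcarbon import CarbonPools, FirePartitionTable, HarvestParams
from borealcarbon.disturbance import (apply_harvest, decay_products,
                                      partition_fire)
from borealcarbon.params import TissueFire

TABLE = FirePartitionTable()
HARVEST = HarvestParams()

pool_mass = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


def make_pools(**kw):
    return CarbonPools(**kw)


class TestPartitionFire:
    def test_green_leaf_woody_fractions(self):
        res = partition_fire(make_pools(green_leaf=1.0), "needleleaf", TABLE)
        assert res.co2_mass == pytest.approx(0.67)
        assert res.litter_gain == pytest.approx(0.32)
        assert res.pools.green_leaf == pytest.approx(0.01)

    def test_green_leaf_nonwoody_fractions(self):
        res = partition_fire(make_pools(green_leaf=1.0), "nonwoody", TABLE)
        assert res.co2_mass == pytest.approx(0.82)
        assert res.litter_gain == pytest.approx(0.17)

    def test_needleleaf_stem_two_units(self):
        res = partition_fire(make_pools(stem=2.0), "needleleaf", TABLE)
        assert res.co2_mass == pytest.approx(0.33)
        assert res.litter_gain == pytest.approx(1.66)
        assert res.pools.stem == pytest.approx(0.01)

    def test_broadleaf_stem_fractions(self):
        res = partition_fire(make_pools(stem=1.0), "broadleaf", TABLE)
        assert res.co2_mass == pytest.approx(0.125)
        assert res.litter_gain == pytest.approx(0.87)

    def test_brown_leaf_fractions(self):
        res = partition_fire(make_pools(brown_leaf=1.0), "needleleaf", TABLE)
        assert res.co2_mass == pytest.approx(0.90)
        assert res.litter_gain == pytest.approx(0.09)

    def test_empty_pools_zero_fluxes(self):
        res = partition_fire(make_pools(), "needleleaf", TABLE)
        assert res.co2_mass == 0.0
        assert res.litter_gain == 0.0
        assert res.pools.total() == 0.0

    def test_roots_all_to_litter(self):
        res = partition_fire(make_pools(root=3.0), "needleleaf", TABLE)
        assert res.co2_mass == 0.0
        assert res.litter_gain == pytest.approx(3.0)
        assert res.pools.root == 0.0
        assert res.pools.litter == pytest.approx(3.0)

    def test_unknown_pft_class_rejected(self):
        with pytest.raises(KeyError, match="conifer"):
            partition_fire(make_pools(stem=1.0), "conifer", TABLE)

    def test_overfull_fractions_rejected_at_construction(self):
        with pytest.raises(ValueError):
            TissueFire(0.7, 0.4)

    def test_sanity_orderings_of_default_table(self):
        """Defaults burn leaves mostly to CO2 but stems mostly to litter."""
        stem = partition_fire(make_pools(stem=1.0), "needleleaf", TABLE)
        leaf = partition_fire(make_pools(green_leaf=1.0), "needleleaf", TABLE)
        assert stem.litter_gain > stem.co2_mass
        assert leaf.co2_mass > leaf.litter_gain

    @given(green=pool_mass, brown=pool_mass, stem=pool_mass, root=pool_mass,
           litter=pool_mass, soil=pool_mass)
    @settings(max_examples=60, deadline=None)
    def test_conservation_and_linearity(self, green, brown, stem, root,
                                        litter, soil):
        pools = make_pools(green_leaf=green, brown_leaf=brown, stem=stem,
                           root=root, litter=litter, soil=soil)
        res = partition_fire(pools, "needleleaf", TABLE)
        total_in = pools.total()
        total_out = res.pools.total() + res.co2_mass
        assert total_out == pytest.approx(total_in, abs=1e-12 * (1 + total_in))
        # linearity: f(2x) = 2 f(x)
        res2 = partition_fire(pools.scaled(2.0), "needleleaf", TABLE)
        assert res2.co2_mass == pytest.approx(2 * res.co2_mass, rel=1e-12)
        assert res2.pools.total() == pytest.approx(2 * res.pools.total(),
                                                   rel=1e-12)


class TestApplyHarvest:
    def test_default_stem_partition(self):
        res = apply_harvest(make_pools(stem=1.0), HARVEST)
        assert res.product_transfer == pytest.approx(0.85)
        assert res.pools.products_short == pytest.approx(0.34)
        assert res.pools.products_long == pytest.approx(0.51)
        assert res.residue_litter == pytest.approx(0.15)

    def test_leaves_and_roots_become_residue(self):
        pools = make_pools(green_leaf=0.5, brown_leaf=0.2, stem=1.0, root=0.8)
        res = apply_harvest(pools, HARVEST)
        assert res.residue_litter == pytest.approx(0.15 + 0.5 + 0.2 + 0.8)
        assert res.pools.litter == pytest.approx(res.residue_litter)

    def test_zero_stem_zero_products(self):
        res = apply_harvest(make_pools(green_leaf=1.0), HARVEST)
        assert res.product_transfer == 0.0

    @given(green=pool_mass, stem=pool_mass, root=pool_mass, soil=pool_mass)
    @settings(max_examples=40, deadline=None)
    def test_conservation_no_atmospheric_flux(self, green, stem, root, soil):
        pools = make_pools(green_leaf=green, stem=stem, root=root, soil=soil)
        res = apply_harvest(pools, HARVEST)
        assert res.pools.total() == pytest.approx(
            pools.total(), abs=1e-12 * (1 + pools.total()))


class TestDecayProducts:
    def test_zero_rate_no_emission(self):
        s, l, em = decay_products(2.0, 3.0, 0.0, 0.0)
        assert (s, l, em) == (2.0, 3.0, 0.0)

    def test_half_life_under_exponential_discretization(self):
        s, _, em = decay_products(1.0, 0.0, math.log(2.0), 0.0)
        assert s == pytest.approx(0.5, rel=1e-12)
        assert em == pytest.approx(0.5, rel=1e-12)

    def test_conservation(self):
        s, l, em = decay_products(1.3, 4.2, 0.2, 0.02)
        assert s + l + em == pytest.approx(1.3 + 4.2, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            decay_products(1.0, 1.0, -0.1, 0.0)
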