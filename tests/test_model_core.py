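"""Annual pool model: CO2 response, yearly step, spin-up, transient runs."""

import math

import numpy as np
import pytest

from borealcarbon import CarbonPools, PftParams
from borealcarbon.model_core import (DOMAIN_PROTOCOL, SITE_PROTOCOL,
                                     YearForcing, co2_response, run_spinup,
                                     run_transient, step_year)
from borealcarbon.synthetic_data import gen_forcing, gen_scenarios, \
    ScenarioSpec


class TestCo2Response:
    @pytest.mark.parametrize("c, c0, gamma, expected", [
        (350.0, 350.0, 0.7, 1.0),  # identity at the reference concentration
        (560.0, 280.0, 0.0, 1.0),  # gamma = 0 switches fertilization off
        (420.0, 289.0, 0.5, 1.0 + 0.5 * math.log(420.0 / 289.0)),
    ])
    def test_values(self, c, c0, gamma, expected):
        assert co2_response(c, c0, gamma) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_historical_range_magnitude(self):
        # across the 289-420 ppm historical range the factor is ~1.187
        assert co2_response(420, 289, 0.5) == pytest.approx(1.1869, abs=1e-4)

    def test_clipped_below_zero(self):
        assert co2_response(1e-6, 400.0, 1.0) == 0.0

    @pytest.mark.parametrize("c, c0", [(0.0, 280.0), (-5.0, 280.0),
                                       (400.0, 0.0)])
    def test_nonpositive_concentration_rejected(self, c, c0):
        with pytest.raises(ValueError):
            co2_response(c, c0, 0.5)


class TestStepYear:
    def test_empty_system_stays_empty(self):
        p = PftParams(gpp_max=0.0)
        pools, age, fx = step_year(CarbonPools(), 10, p,
                                   YearForcing(0.0, 277.0))
        assert pools.total() == 0.0
        assert fx.gpp == fx.ra == fx.rh == 0.0

    def test_carbon_closure_single_step(self, params, equilibrium):
        pools = equilibrium.pools
        new, _, fx = step_year(pools, equilibrium.age, params,
                               YearForcing(1.3, 350.0))
        nbp = fx.nep - fx.product_emission  # no fire at tile level
        assert new.total() - pools.total() == pytest.approx(
            nbp, rel=1e-9, abs=1e-12)

    def test_equilibrium_is_fixed_point(self, params, equilibrium):
        new, _, fx = step_year(equilibrium.pools, equilibrium.age, params,
                               YearForcing(0.0, params.c0_ppm))
        assert abs(fx.nep) < 1e-4
        assert abs(new.total() - equilibrium.pools.total()) < 1e-4

    def test_nan_forcing_rejected(self, params):
        with pytest.raises(ValueError):
            step_year(CarbonPools(soil=1.0), 5, params,
                      YearForcing(float("nan"), 350.0))


class TestSpinup:
    def test_fast_configuration_converges_quickly(self):
        p = PftParams(tau_green_leaf=1.5, tau_brown_leaf=1.0, tau_stem=3.0,
                      tau_root=2.0, k_litter=0.5, k_soil=0.3, tau_rec=2.0)
        f = gen_forcing(range(1750, 1800), 1, seed=0, ar1_sd=0.0,
                        warming_rate=0.0)
        state = run_spinup(p, f, 0)
        assert state.cycles <= 10
        # returned state passes the fixed-point check
        new, _, fx = step_year(state.pools, state.age, p,
                               YearForcing(0.0, p.c0_ppm))
        assert abs(new.total() - state.pools.total()) < 1e-4

    def test_infinite_tolerance_returns_after_one_cycle(self, params,
                                                        quiet_forcing):
        state = run_spinup(params, quiet_forcing, 0, tol=float("inf"))
        assert state.cycles == 1

    def test_deterministic(self, params, quiet_forcing):
        a = run_spinup(params, quiet_forcing, 0)
        b = run_spinup(params, quiet_forcing, 0)
        assert a.pools.as_dict() == b.pools.as_dict()
        assert a.age == b.age

    def test_nonconvergence_names_slowest_pool(self, params, quiet_forcing):
        with pytest.raises(RuntimeError, match="soil|stem"):
            run_spinup(params, quiet_forcing, 0, tol=0.0, max_cycles=3)

    def test_replaying_cycle_changes_total_less_than_tol(self, params,
                                                         quiet_forcing,
                                                         equilibrium):
        pools, age = equilibrium.pools.copy(), equilibrium.age
        before = pools.total()
        for i in range(25):
            pools, age, _ = step_year(
                pools, age, params,
                YearForcing(float(quiet_forcing.tair_anomaly[i, 0]),
                            params.c0_ppm))
        assert abs(pools.total() - before) < 1e-4


class TestTransient:
    def test_counterfactual_limit_single_tile_no_fire(self, params,
                                                      equilibrium,
                                                      trend_forcing):
        res = run_transient(equilibrium, params,
                            trend_forcing.without_disturbance(),
                            DOMAIN_PROTOCOL)
        assert np.all(res.ledger.fire_co2 == 0.0)
        assert np.all(res.tile_count == 1)
        single = run_transient(equilibrium, params,
                               trend_forcing.without_disturbance(),
                               DOMAIN_PROTOCOL, max_tiles=1)
        np.testing.assert_allclose(res.ledger.nbp, single.ledger.nbp,
                                   rtol=0, atol=0)

    def test_whole_run_conservation(self, params, equilibrium,
                                    small_ensemble):
        _, scens = small_ensemble
        res = run_transient(equilibrium, params, scens["mean_raster"],
                            DOMAIN_PROTOCOL, cell=0)
        assert res.closure_residual() < 1e-6

    def test_burn_recovery_shape(self, params, quiet_forcing, equilibrium):
        """A single 100% burn: NEP collapses below zero, the source-sink
        transition occurs within ~20 yr, and GPP plateaus by ~50-60 yr."""
        f = quiet_forcing.without_disturbance()
        f.burned_fraction[f.index_of(1900), 0] = 1.0
        res = run_transient(equilibrium, params, f, DOMAIN_PROTOCOL,
                            max_tiles=1, co2_transient=False)
        i0 = int(np.where(res.ledger.years == 1900)[0][0])
        nep = res.ledger.nep[i0 + 1:]
        assert nep[0] < 0.0
        cross = int(np.argmax(nep > 0))
        assert 0 < cross <= 20
        gpp = res.ledger.gpp[i0 + 1:i0 + 81]
        assert np.all(np.diff(gpp) > -1e-12)  # monotone recovery
        assert gpp[54] > 0.95 * gpp[-1]  # plateau by ~55 yr

    def test_short_forcing_rejected(self, params, equilibrium):
        short = gen_forcing(range(1900, 1950), 1, seed=0)
        with pytest.raises(ValueError, match="cover"):
            run_transient(equilibrium, params, short, DOMAIN_PROTOCOL)

    def test_nbp_nondecreasing_in_gamma_under_rising_co2(self, equilibrium,
                                                         trend_forcing):
        means = []
        for gamma in (0.0, 0.25, 0.5, 0.75):
            p = PftParams(gamma=gamma)
            res = run_transient(equilibrium, p,
                                trend_forcing.without_disturbance(),
                                DOMAIN_PROTOCOL)
            means.append(res.ledger.window_mean(1960, 2020, "nbp"))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))

    def test_ledger_identities_hold(self, params, equilibrium,
                                    small_ensemble):
        _, scens = small_ensemble
        res = run_transient(equilibrium, params, scens["inferred_vector"],
                            DOMAIN_PROTOCOL, cell=1)
        led = res.ledger
        np.testing.assert_allclose(led.er, led.ra + led.rh, rtol=1e-12)
        np.testing.assert_allclose(led.nep, led.gpp - led.er, rtol=1e-12)
        np.testing.assert_allclose(
            led.nbp, led.nep - led.fire_co2 - led.product_emission,
            rtol=1e-12, atol=1e-15)
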