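"""Factorial run matrix, NBP attribution, and CO2 sensitivity."""

import numpy as np
import pytest

from borealcarbon import PftParams
from borealcarbon.factorial import (AttributionResult, attribute_nbp,
                                    build_run_matrix, co2_sensitivity,
                                    ensemble_attribution, run_factorial)
from borealcarbon.model_core import DOMAIN_PROTOCOL
from borealcarbon.synthetic_data import ScenarioSpec, gen_scenarios

WINDOW = (2002, 2022)


@pytest.fixture(scope="module")
def factorial_runs(small_ensemble):
    _, scens = small_ensemble
    return run_factorial(PftParams(), scens["mean_raster"],
                         build_run_matrix(), DOMAIN_PROTOCOL)


class TestBuildRunMatrix:
    def test_three_factors_give_four_runs(self):
        runs = build_run_matrix(("climate", "co2", "disturbance"))
        assert [r.name for r in runs] == ["ALL", "climate_fixed",
                                          "co2_fixed", "no_disturbance"]

    def test_pre_boundary_variant_adds_fifth_run(self):
        runs = build_run_matrix(pre_boundary_year=1918)
        assert len(runs) == 5
        assert runs[-1].disturbance_start_year == 1918

    def test_deterministic(self):
        assert build_run_matrix() == build_run_matrix()

    def test_unknown_factor_rejected(self):
        with pytest.raises(KeyError, match="nitrogen"):
            build_run_matrix(("climate", "nitrogen"))


class TestAttribution:
    def test_channel_bookkeeping_identity(self):
        """Net disturbance is exactly the sum of its three channels:
        recovery 80 with immediate+decomposition -128 nets to -48."""
        attr = AttributionResult(
            window=(2002, 2022),
            contributions={"climate": -61.0, "co2": 152.0,
                           "dist_immediate": -90.0,
                           "dist_decomposition": -38.0,
                           "dist_recovery": 80.0},
            closure_residual=0.0)
        assert attr.contributions["dist_immediate"] \
            + attr.contributions["dist_decomposition"] == -128.0
        assert attr.net_disturbance == pytest.approx(-48.0)

    def test_no_disturbance_everywhere_zero_channels(self, small_ensemble):
        _, scens = small_ensemble
        runs = run_factorial(PftParams(),
                             scens["mean_raster"].without_disturbance(),
                             build_run_matrix(), DOMAIN_PROTOCOL)
        attr = attribute_nbp(runs, WINDOW)
        for ch in ("dist_immediate", "dist_decomposition", "dist_recovery"):
            assert attr.contributions[ch] == pytest.approx(0.0, abs=1e-12)
        assert attr.closure_residual == pytest.approx(0.0, abs=1e-12)

    def test_fixed_factor_contributes_exactly_zero(self, small_ensemble):
        """If the ALL run itself holds CO2 fixed, the CO2 channel is 0."""
        _, scens = small_ensemble
        f = scens["mean_raster"]
        runs = run_factorial(
            PftParams(), f,
            [r for r in build_run_matrix() if r.name != "ALL"],
            DOMAIN_PROTOCOL)
        runs["ALL"] = runs["co2_fixed"]
        attr = attribute_nbp(runs, WINDOW)
        assert attr.contributions["co2"] == 0.0

    def test_closure_within_one_percent(self, factorial_runs):
        attr = attribute_nbp(factorial_runs, WINDOW)
        net = attr.net_disturbance
        assert abs(attr.closure_residual) <= 0.01 * max(abs(net), 1e-12)

    def test_forest_mask_restricts_cells(self, factorial_runs):
        full = attribute_nbp(factorial_runs, WINDOW)
        masked = attribute_nbp(factorial_runs, WINDOW,
                               forest_mask=np.array([True, False, True,
                                                     False]))
        assert masked.contributions != full.contributions

    def test_missing_run_rejected(self, factorial_runs):
        incomplete = {k: v for k, v in factorial_runs.items() if k != "ALL"}
        with pytest.raises(KeyError, match="ALL"):
            attribute_nbp(incomplete, WINDOW)


class TestEnsembleAttribution:
    def test_bounds_bracket_the_mean(self, small_ensemble):
        _, scens = small_ensemble
        per = {}
        for name, f in scens.items():
            runs = run_factorial(PftParams(), f, build_run_matrix(),
                                 DOMAIN_PROTOCOL)
            per[name] = attribute_nbp(runs, WINDOW)
        ens = ensemble_attribution(per)
        for k, v in ens.contributions.items():
            lo, hi = ens.bounds[k]
            assert lo <= v <= hi

    def test_pre_boundary_spread_exceeds_observation_era_spread(
            self, small_ensemble):
        """Mid-century NBP uncertainty from the pre-1918 assumption
        exceeds the observation-era (raster vs vector) uncertainty."""
        _, scens = small_ensemble
        means = {}
        for name, f in scens.items():
            runs = run_factorial(PftParams(), f,
                                 build_run_matrix(("disturbance",)),
                                 DOMAIN_PROTOCOL)
            m = (runs["ALL"].years >= 1940) & (runs["ALL"].years <= 1960)
            means[name] = runs["ALL"].fluxes["nbp"][m].mean()
        pre_spread = abs(
            (means["inferred_raster"] + means["inferred_vector"]) / 2
            - (means["mean_raster"] + means["mean_vector"]) / 2)
        obs_spread = abs(
            (means["mean_vector"] + means["inferred_vector"]) / 2
            - (means["mean_raster"] + means["inferred_raster"]) / 2)
        assert pre_spread > obs_spread


class TestCo2Sensitivity:
    def test_arithmetic_definition(self):
        # contribution of 52 over a mean excess of 43.3 ppm is 1.2 per ppm
        assert 52.0 / 43.3 == pytest.approx(1.2, abs=0.01)

    def test_zero_excess_rejected(self, small_ensemble):
        _, scens = small_ensemble
        f = scens["mean_raster"]
        runs = run_factorial(PftParams(), f, build_run_matrix(),
                             DOMAIN_PROTOCOL)
        with pytest.raises(ValueError, match="excess"):
            co2_sensitivity(runs, (1750, 1750), f, PftParams().c0_ppm)

    def test_positive_sensitivity_under_rising_co2(self, factorial_runs,
                                                   small_ensemble):
        _, scens = small_ensemble
        sens = co2_sensitivity(factorial_runs, WINDOW,
                               scens["mean_raster"], PftParams().c0_ppm)
        assert sens > 0

    def test_scales_with_gamma_at_small_excess(self, small_ensemble):
        """The CO2 channel is ~linear in gamma for small CO2 excess."""
        _, scens = small_ensemble
        f = scens["mean_raster"]
        window = (1900, 1920)  # small CO2 excess over preindustrial
        sens = {}
        for gamma in (0.25, 0.5):
            runs = run_factorial(PftParams(gamma=gamma), f,
                                 build_run_matrix(("co2",)), DOMAIN_PROTOCOL)
            sens[gamma] = co2_sensitivity(runs, window, f,
                                          PftParams().c0_ppm)
        assert sens[0.5] / sens[0.25] == pytest.approx(2.0, rel=0.15)
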