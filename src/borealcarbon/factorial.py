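"""Factorial experiment matrix and windowed NBP attribution.

The attribution decomposes the net biome productivity of the full (ALL)
run into contributions from climate, CO2 fertilization, and three
disturbance channels over an averaging window:

* climate       = mean(NBP_ALL - NBP_climate-fixed)
* co2           = mean(NBP_ALL - NBP_co2-fixed)
* dist_immediate      = -mean(fire CO2 + product emissions)   [ALL ledger]
* dist_decomposition  = -mean(Rh_ALL - Rh_no-disturbance)
* dist_recovery       =  mean((GPP - Ra)_ALL - (GPP - Ra)_no-disturbance)

net_disturbance is the sum of the three disturbance channels, and the
closure residual (NBP_ALL - NBP_no-disturbance) - net_disturbance is
always reported. With this bookkeeping the three channels sum to the
run-differenced disturbance effect up to floating-point error, because
NBP = (GPP - Ra) - Rh - fire CO2 - product emissions identically.
Running the attribution once per disturbance scenario yields min/max
ensemble brackets per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcing import Forcing
from .model_core import DOMAIN_PROTOCOL, DomainResult, RunProtocol, \
    SpinupState, run_domain
from .params import PftParams

KNOWN_FACTORS = ("climate", "co2", "disturbance")
DISTURBANCE_CHANNELS = ("dist_immediate", "dist_decomposition",
                        "dist_recovery")


@dataclass(frozen=True)
class RunSpec:
    """One factorial run: which drivers are transient vs held at their
    spin-up state."""

    name: str
    climate_transient: bool = True
    co2_transient: bool = True
    disturbance: bool = True
    disturbance_start_year: int | None = None


def build_run_matrix(factors: tuple[str, ...] = KNOWN_FACTORS,
                     pre_boundary_year: int | None = None
                     ) -> list[RunSpec]:
    """ALL plus, per factor, a run with that factor held at its spin-up
    state; optionally a variant with disturbance zeroed before a
    boundary year. Deterministic."""
    for f in factors:
        if f not in KNOWN_FACTORS:
            raise KeyError(f"unknown factor {f!r}; known: {KNOWN_FACTORS}")
    runs = [RunSpec("ALL")]
    if "climate" in factors:
        runs.append(RunSpec("climate_fixed", climate_transient=False))
    if "co2" in factors:
        runs.append(RunSpec("co2_fixed", co2_transient=False))
    if "disturbance" in factors:
        runs.append(RunSpec("no_disturbance", disturbance=False))
    if pre_boundary_year is not None:
        runs.append(RunSpec(f"no_disturbance_before_{pre_boundary_year}",
                            disturbance_start_year=pre_boundary_year))
    return runs


def run_factorial(params: PftParams, forcing: Forcing,
                  runs: list[RunSpec],
                  protocol: RunProtocol = DOMAIN_PROTOCOL,
                  spinup_tol: float = 1e-4) -> dict[str, DomainResult]:
    """Execute a factorial run matrix on one disturbance scenario.

    Spin-up states are shared across runs (spin-up sees neither CO2
    trends nor disturbance, so the equilibrium is common)."""
    cache: dict[int, SpinupState] = {}
    out: dict[str, DomainResult] = {}
    for spec in runs:
        out[spec.name] = run_domain(
            params, forcing, protocol,
            disturbance=spec.disturbance,
            disturbance_start_year=spec.disturbance_start_year,
            climate_transient=spec.climate_transient,
            co2_transient=spec.co2_transient,
            spinup_tol=spinup_tol, name=spec.name, spinup_cache=cache)
    return out


@dataclass
class AttributionResult:
    """Per-factor NBP contributions over an averaging window.

    Units follow the input fluxes (kg C m^-2 yr^-1 at cell scale, or
    Tg C yr^-1 after national aggregation via `scale`)."""

    window: tuple[int, int]
    contributions: dict[str, float]
    closure_residual: float
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def net_disturbance(self) -> float:
        return sum(self.contributions[c] for c in DISTURBANCE_CHANNELS
                   if c in self.contributions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.contributions.items():
            lo, hi = self.bounds.get(k, (np.nan, np.nan))
            rows.append({"factor": k, "window_start": self.window[0],
                         "window_end": self.window[1], "contribution": v,
                         "lower": lo, "upper": hi,
                         "closure_residual": self.closure_residual})
        rows.append({"factor": "net_disturbance",
                     "window_start": self.window[0],
                     "window_end": self.window[1],
                     "contribution": self.net_disturbance,
                     "lower": np.nan, "upper": np.nan,
                     "closure_residual": self.closure_residual})
        return pd.DataFrame(rows)


def _window_mean(arr: np.ndarray, years: np.ndarray,
                 window: tuple[int, int],
                 cells: np.ndarray | None) -> float:
    mask = (years >= window[0]) & (years <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} outside run years")
    sub = arr[mask]
    if cells is not None:
        sub = sub[:, cells]
    return float(sub.mean())


def attribute_nbp(runs: dict[str, DomainResult], window: tuple[int, int],
                  forest_mask: np.ndarray | None = None,
                  scale: float = 1.0) -> AttributionResult:
    """Attribute windowed NBP to climate, CO2, and disturbance channels.

    `runs` must contain "ALL", "climate_fixed", "co2_fixed" and
    "no_disturbance" sharing years and cells. `forest_mask` restricts
    the cell average (boolean mask or index array); `scale` converts
    cell-mean fluxes to reporting units (e.g., Tg C yr^-1)."""
    required = ("ALL", "climate_fixed", "co2_fixed", "no_disturbance")
    for r in required:
        if r not in runs:
            raise KeyError(f"attribution requires run {r!r}")
    all_run = runs["ALL"]
    years = all_run.years
    for r in required[1:]:
        if not np.array_equal(runs[r].years, years):
            raise ValueError("factorial runs must share the year axis")
        if runs[r].fluxes["nbp"].shape != all_run.fluxes["nbp"].shape:
            raise ValueError("factorial runs must share the cell axis")
    cells = None
    if forest_mask is not None:
        forest_mask = np.asarray(forest_mask)
        cells = (np.nonzero(forest_mask)[0] if forest_mask.dtype == bool
                 else forest_mask)

    def wm(run: str, fld: str) -> float:
        return _window_mean(runs[run].fluxes[fld], years, window, cells)

    climate = wm("ALL", "nbp") - wm("climate_fixed", "nbp")
    co2 = wm("ALL", "nbp") - wm("co2_fixed", "nbp")
    immediate = -(wm("ALL", "fire_co2") + wm("ALL", "product_emission"))
    decomposition = -(wm("ALL", "rh") - wm("no_disturbance", "rh"))
    recovery = ((wm("ALL", "gpp") - wm("ALL", "ra"))
                - (wm("no_disturbance", "gpp") - wm("no_disturbance", "ra")))
    dist_total = wm("ALL", "nbp") - wm("no_disturbance", "nbp")
    net = immediate + decomposition + recovery
    contributions = {
        "climate": climate * scale,
        "co2": co2 * scale,
        "dist_immediate": immediate * scale,
        "dist_decomposition": decomposition * scale,
        "dist_recovery": recovery * scale,
    }
    return AttributionResult(window=window, contributions=contributions,
                             closure_residual=(dist_total - net) * scale)


def ensemble_attribution(per_scenario: dict[str, AttributionResult]
                         ) -> AttributionResult:
    """Ensemble-mean attribution with min/max brackets per factor."""
    if not per_scenario:
        raise ValueError("no scenarios given")
    members = list(per_scenario.values())
    window = members[0].window
    keys = members[0].contributions.keys()
    contributions = {}
    bounds = {}
    for k in keys:
        vals = [m.contributions[k] for m in members]
        contributions[k] = float(np.mean(vals))
        bounds[k] = (float(np.min(vals)), float(np.max(vals)))
    residual = float(np.mean([m.closure_residual for m in members]))
    return AttributionResult(window=window, contributions=contributions,
                             closure_residual=residual, bounds=bounds)


def co2_sensitivity(runs: dict[str, DomainResult], window: tuple[int, int],
                    forcing: Forcing, c0_ppm: float,
                    forest_mask: np.ndarray | None = None,
                    scale: float = 1.0) -> float:
    """NBP sensitivity to CO2 fertilization, per ppm of atmospheric
    increase over the reference concentration within the window.

    Requires only the "ALL" and "co2_fixed" runs."""
    for r in ("ALL", "co2_fixed"):
        if r not in runs:
            raise KeyError(f"co2_sensitivity requires run {r!r}")
    years = runs["ALL"].years
    cells = None
    if forest_mask is not None:
        forest_mask = np.asarray(forest_mask)
        cells = (np.nonzero(forest_mask)[0] if forest_mask.dtype == bool
                 else forest_mask)
    contribution = (
        _window_mean(runs["ALL"].fluxes["nbp"], years, window, cells)
        - _window_mean(runs["co2_fixed"].fluxes["nbp"], years, window,
                       cells)) * scale
    mask = (forcing.years >= window[0]) & (forcing.years <= window[1])
    excess = float(forcing.co2_ppm[mask].mean()) - c0_ppm
    if abs(excess) < 1e-12:
        raise ValueError("CO2 excess over the reference concentration is "
                         "zero in the window; sensitivity undefined")
    return contribution / excess
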