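"""National aggregation, rolling-window trend tests, and source-sink
transition estimation.

Fluxes are aggregated to national totals by area weighting
(kg C m^-2 yr^-1 x m^2 -> Tg C yr^-1; pools -> Pg C), with CO2
equivalents at the molar mass ratio 44/12. Trend testing fits ordinary
least squares to every sliding window (default 15 yr) with a two-sided
t-test on the slope; windows whose significant negative slope coincides
with a sign change of the running mean are flagged. The source-sink
crossing year extrapolates a linear fit to the last window of the
running-mean series to its zero crossing, per ensemble member.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

KG_PER_TG = 1.0e9
KG_PER_PG = 1.0e12
CO2_MASS_RATIO = 44.0 / 12.0


def c_mass_to_co2(mass_c: float, ratio: float = CO2_MASS_RATIO) -> float:
    """Convert a carbon mass to CO2-equivalent mass (same unit prefix)."""
    return mass_c * ratio


def national_summary(cell_fluxes: dict[str, np.ndarray],
                     cell_pools: dict[str, np.ndarray],
                     cell_areas: np.ndarray) -> pd.DataFrame:
    """Area-weighted national totals.

    `cell_fluxes` values are per-cell fluxes (kg C m^-2 yr^-1) -> Tg C
    yr^-1 (plus Tg CO2 yr^-1); `cell_pools` are per-cell densities
    (kg C m^-2) -> Pg C. Linear in the inputs and invariant to cell
    ordering."""
    areas = np.asarray(cell_areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("cell areas must be > 0")
    rows = []
    for name, vals in cell_fluxes.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != areas.shape:
            raise ValueError(f"flux {name!r} does not match cell areas")
        tg = float((vals * areas).sum()) / KG_PER_TG
        rows.append({"quantity": name, "kind": "flux", "value": tg,
                     "unit": "Tg C yr-1",
                     "co2_equivalent_Tg": c_mass_to_co2(tg)})
    for name, vals in cell_pools.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != areas.shape:
            raise ValueError(f"pool {name!r} does not match cell areas")
        pg = float((vals * areas).sum()) / KG_PER_PG
        rows.append({"quantity": name, "kind": "pool", "value": pg,
                     "unit": "Pg C", "co2_equivalent_Tg": np.nan})
    return pd.DataFrame(rows)


@dataclass
class TrendWindowResult:
    start_year: int
    end_year: int
    slope: float
    p_value: float
    significant_negative: bool
    flag_sign_change: bool


def running_mean(series: np.ndarray, window: int = 10) -> np.ndarray:
    """Trailing running mean; first window-1 entries are NaN."""
    series = np.asarray(series, dtype=float)
    out = np.full(series.shape, np.nan)
    if len(series) >= window:
        kernel = np.ones(window) / window
        out[window - 1:] = np.convolve(series, kernel, mode="valid")
    return out


def _ols_windows(values: np.ndarray, window: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-window OLS slope and two-sided t-test p-value."""
    wins = sliding_window_view(values, window)
    x = np.arange(window, dtype=float)
    x = x - x.mean()
    sxx = float((x ** 2).sum())
    y_mean = wins.mean(axis=1, keepdims=True)
    slope = (wins * x).sum(axis=1) / sxx
    resid = wins - y_mean - slope[:, None] * x
    dof = window - 2
    sse = (resid ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        t = np.where(se > 0, slope / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    # zero slope with zero variance: no evidence of trend
    p = np.where((se == 0) & (slope == 0), 1.0, p)
    return slope, p


def rolling_trend(years: np.ndarray, series: np.ndarray, window: int = 15,
                  alpha: float = 0.05, smooth_window: int = 10
                  ) -> list[TrendWindowResult]:
    """OLS slope + two-sided t-test per sliding window.

    Flags windows where a significant negative slope coincides with a
    sign change of the `smooth_window`-year running mean inside the
    window (the "would flip the running-mean sign" condition)."""
    years = np.asarray(years, dtype=int)
    series = np.asarray(series, dtype=float)
    if len(series) < window:
        raise ValueError(
            f"series length {len(series)} shorter than window {window}")
    slope, p = _ols_windows(series, window)
    rmean = running_mean(series, smooth_window)
    results = []
    for i in range(len(slope)):
        j = i + window - 1
        sig_neg = bool(p[i] < alpha and slope[i] < 0)
        seg = rmean[i:j + 1]
        seg = seg[~np.isnan(seg)]
        crosses = bool(len(seg) > 0 and seg.max() > 0 >= seg.min())
        results.append(TrendWindowResult(
            start_year=int(years[i]), end_year=int(years[j]),
            slope=float(slope[i]), p_value=float(p[i]),
            significant_negative=sig_neg,
            flag_sign_change=sig_neg and crosses))
    return results


def trend_results_frame(results: list[TrendWindowResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass
class CrossingEstimate:
    """Source-sink transition year estimated across an ensemble."""

    member_years: dict[str, float]  # crossing year per crossing member
    non_crossing: list[str]  # members with no downward zero crossing

    @property
    def mean_year(self) -> float:
        if not self.member_years:
            return float("nan")
        return float(np.mean(list(self.member_years.values())))

    @property
    def sd_years(self) -> float:
        if len(self.member_years) < 2:
            return float("nan")
        return float(np.std(list(self.member_years.values()), ddof=1))


def _member_crossing(years: np.ndarray, series: np.ndarray,
                     trend_window: int, smooth_window: int) -> float | None:
    """Zero crossing of the linear trend fitted to the last trend_window
    points of the centered running mean; None if the fit does not cross
    going downward.

    Window means are fitted against their true (possibly half-year)
    centers, so an exactly linear series yields its analytic crossing."""
    series = np.asarray(series, dtype=float)
    if len(series) < smooth_window:
        raise ValueError("series shorter than the smoothing window")
    kernel = np.ones(smooth_window) / smooth_window
    rm = np.convolve(series, kernel, mode="valid")
    centers = years[:len(rm)].astype(float) + (smooth_window - 1) / 2.0
    if len(rm) < trend_window:
        raise ValueError("running-mean series shorter than the trend window")
    x = centers[-trend_window:]
    y = rm[-trend_window:]
    slope, intercept = np.polyfit(x, y, 1)
    # slopes indistinguishable from zero (flat series up to round-off)
    # cannot produce a downward crossing
    tol = 1e-12 * (1.0 + float(np.abs(y).mean()))
    if slope >= -tol:
        return None
    return float(-intercept / slope)


def crossing_year(ensemble: dict[str, tuple[np.ndarray, np.ndarray]],
                  trend_window: int = 15,
                  smooth_window: int = 10) -> CrossingEstimate:
    """Estimate the source-sink transition year for each ensemble member.

    Each member maps a name to (years, annual NBP series). Members whose
    extrapolated trend never crosses zero downward are reported in
    `non_crossing`, never silently dropped."""
    member_years: dict[str, float] = {}
    non_crossing: list[str] = []
    for name, (yrs, series) in ensemble.items():
        yrs = np.asarray(yrs, dtype=int)
        series = np.asarray(series, dtype=float)
        xc = _member_crossing(yrs, series, trend_window, smooth_window)
        if xc is None:
            non_crossing.append(name)
        else:
            member_years[name] = xc
    return CrossingEstimate(member_years=member_years,
                            non_crossing=non_crossing)
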