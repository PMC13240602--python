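# Methods

## Model structure

The simulator is an annual-timestep box model of eight carbon
compartments per age tile: green leaf, brown (standing-dead) leaf, stem,
root, litter, soil, and short- and long-lived wood products, all in
kg C m⁻². It deliberately omits energy and water balance, phenology,
nitrogen, peatlands, and sub-annual photosynthesis: the object of study
is the disturbance-recovery *analysis chain* — partitioning, tiling,
evaluation, attribution — not land-surface physics, and every driver the
chain consumes is annual.

### Annual update

For a tile of age *a* under temperature anomaly ΔT (°C) and CO₂
concentration *c* (ppm):

* `GPP = gpp_max · vcmax_scale · (1 − e^(−a/τ_rec)) · e^(β·ΔT) ·
  max(0, 1 + γ·ln(c/c₀))`
* maintenance respiration per live pool: `rs · r_p · Q10^(ΔT/10) ·
  pool_p`; growth respiration: `rs · g · GPP`; Ra is their sum
* the allocatable assimilate `GPP·(1 − rs·g)` is split
  leaf/stem/root by fixed fractions
* turnover: green leaf → brown leaf → litter; stem, root → litter;
  litter decays at `k_litter·Q10^(ΔT/10)` with a humified fraction to
  soil, the rest to Rh; soil decays at `k_soil·Q10^(ΔT/10)` to Rh
* product pools decay as exact exponentials (`pool·e^(−k)` per year),
  the loss being an atmospheric source

The scheme is explicit Euler with one structural safeguard: live pools
pay their own maintenance (rate × pool) while new growth comes only from
GPP, so no pool can be driven negative as long as each pool's total
annual loss rate stays below 1 — a bound the parameter validator
enforces at construction (checked at a +5 °C Q10 excursion). A negative
pool therefore indicates an internal error and raises; it is never
clipped. The update conserves carbon identically:
ΔC = GPP − Ra − Rh − product emissions = NBP per tile-year, and the
transient runner audits whole-run closure (observed ≲ 1e-14 relative on
centennial runs).

### CO₂ fertilization and its downregulation

The factor `1 + γ·ln(c/c₀)` is the simplest single-parameter form in
which γ damps the logarithmic GPP response; γ = 0.5 halves the
unmodified response, consistent with the degree of photosynthetic
downregulation observed in nutrient-limited seedlings. The form is
isolated behind `co2_response` so an alternative parameterization can be
swapped in one place. c₀ is the concentration of the protocol's spin-up
year (site protocol 1700, domain protocol 1750), because spin-up holds
CO₂ there.

### Parameter defaults and rationale

| parameter | default | unit | rationale |
|---|---|---|---|
| gpp_max | 0.9 | kg C m⁻² yr⁻¹ | mature boreal/temperate GPP ceiling (≈1.0 with the carboxylation scaling) |
| vcmax_scale | 1.11 | – | +11 % carboxylation-capacity calibration |
| respiration_scale | 0.75 | – | −25 % across-the-board respiration calibration |
| γ | 0.5 | – | CO₂ downregulation (above) |
| τ_rec | 18 | yr | GPP reaches ~95 % of plateau ≈55 yr post-disturbance, matching chronosequence behaviour |
| β_gpp | 0.02 | °C⁻¹ | mild warming benefit to uptake |
| Q10 | 2.0 | – | canonical respiration sensitivity; with β_gpp chosen so warming raises respiration more than uptake (the climate attribution channel is a net source) |
| allocation leaf/stem/root | 0.35/0.35/0.30 | – | woody-stand partitioning |
| turnover leaf/brown/stem/root | 3/1/45/10 | yr | needleleaf retention; stand-scale stem residence |
| k_litter, k_soil | 0.15, 0.02 | yr⁻¹ | litter decades⁻¹, soil ~50 yr residence |
| humification | 0.30 | – | fraction of litter decay stabilized as soil |

At equilibrium under preindustrial forcing these defaults give AGB
≈ 9 kg C m⁻², litter ≈ 3, soil ≈ 8 kg C m⁻² — plausible for productive
boreal/temperate forest (the national soil analogue is an
underestimate, as the model carries no peatland pool).

### Fire, harvest, and tiling

Fire partitioning is per tissue × PFT class with the fractions listed in
the README; the small retained-live residuals (1 − CO₂ − litter
fractions) seed the new age-0 tile, standing in for fire survivors and
standing dead structure. Values not part of the partition table — root
fire fate (no combustion, all killed roots to litter), litter (0.10) and
soil (0.02) combustion fractions, and the entire harvest partition
(0.85 of stem removed, split 0.4/0.6 into 5-yr and 50-yr product pools)
— are package calibration choices exposed in configuration, not
literature constants.

Disturbed area is drawn proportionally from all tiles by default
(an oldest-first policy is available); each year's disturbed fragments
are pooled into a single new age-0 tile. When the count exceeds
`max_tiles` (12), the pair of tiles closest in age merges (ties: the
smaller combined area), with area-weighted pools and age — nearest-age
merging is chosen because age is the state variable that drives recovery
fluxes, so it minimizes the flux error introduced by merging. Monthly
disaggregation of annual burned area by a fixed fire-season climatology
is reporting-only; pools never see months.

### Spin-up and run protocols

Spin-up loops the first 25 years of the climate driver with CO₂ held at
c₀, starting from near-bare ground, until total carbon changes by less
than 1e-4 kg C m⁻² per cycle (max 400 cycles; non-convergence raises,
naming the slowest pool). Transient runs loop the same 25-yr climate
until 1900 while CO₂ varies, then use fully transient forcing; the site
protocol starts in 1700, the domain protocol in 1750, both ending 2023.
Site runs are single-tile (a stand-replacing event covers the whole
site); domain runs use 12 dynamic tiles. Years are integers; no
calendar logic.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not any real geography:

* **Climate**: cell-independent AR(1) temperature anomalies (φ = 0.5,
  σ = 0.6 °C) plus a shared 0.025 °C yr⁻¹ linear warming from 1950.
  The precipitation index is generated but unused by the flux model.
* **CO₂**: monotone power ramp 289 → 420 ppm over 1900–2023, linear
  from 277 ppm before 1900.
* **Disturbance ensemble**: burned fractions are clipped lognormal
  (mean 0.5 % yr⁻¹, σ_log = 0.8 — burned area is strongly right-skewed);
  harvest is clipped normal (0.2 % yr⁻¹). The 2×2 ensemble shares its
  noise fields, so members differ only by additive offsets: "inferred"
  members add 0.8 % yr⁻¹ before 1918 (the 3.2 Mha yr⁻¹ national
  analogue over the 400 Mha nominal domain), "vector" members add
  0.175 % yr⁻¹ (0.7 Mha yr⁻¹) in the observation era. Cells carry equal
  nominal area (400 Mha / n_cells), which is how Mha offsets map to
  fractions.
* **Pseudo-towers**: model truth plus iid Gaussian noise (GPP/ER 0.10,
  NEP 0.06 kg C m⁻² yr⁻¹, AGB 0.6 kg C m⁻²), magnitudes comparable to
  eddy-covariance and biometric uncertainty.

What passing tests on these data do **not** show: skill against real
towers or inventories. The generators have no spatial autocorrelation
of burns, no drought or precipitation control on fluxes, no
non-stand-replacing disturbance, and iid observation noise without the
energy-balance-closure and gap-filling structure of real flux data.

## Evaluation and attribution choices

* **ΔMAE protocol**: ΔMAE = MAE(counterfactual) − MAE(factual) per site
  × variable; each site contributes one equal-weight summary regardless
  of record length (space-for-time substitution). Sites are positioned
  at mean observation year minus disturbance year; for multi-event
  sites the most recent event would anchor the axis. Binned aggregation
  (default 5-yr bins) replaces the local-regression smoothing that a
  visualization would use.
* **Factorial attribution**: climate and CO₂ channels are run
  differences against single-factor-fixed runs; the immediate
  disturbance channel is read off the ALL ledger
  (−(fire CO₂ + product emissions)); decomposition and recovery are run
  differences of Rh and GPP−Ra against the no-disturbance run. Because
  NBP ≡ (GPP−Ra) − Rh − fire − products, the three disturbance channels
  sum to NBP_ALL − NBP_no-disturbance identically, and the reported
  closure residual measures only floating-point error. With the
  monotone age-recovery curve used here, a disturbed landscape cannot
  out-produce its never-disturbed counterfactual, so at this model's
  reduced complexity the "recovery" channel is negative and
  "decomposition" positive when measured against a no-disturbance
  baseline — the channel *bookkeeping* is general, but channel signs
  need not match a full demographic model, where mature-stand
  productivity decline makes regrowth a net sink. The ensemble bracket
  structure (mid-century spread dominated by the pre-1918 assumption,
  shrinking once observations constrain the drivers) is reproduced.
* **Trends**: per-window OLS with a two-sided t-test on the slope;
  plain OLS, no autocorrelation correction, and no multiple-testing
  correction across (overlapping) windows — raw window p-values are
  reported. A zero-variance window is reported as slope 0, p = 1. The
  sign-change flag marks significant negative windows whose 10-yr
  running mean changes sign within the window.
* **Crossing year**: per ensemble member, a line is fitted to the last
  15 points of the 10-yr running mean — against the true (half-year)
  window centers, so an exactly linear series recovers its analytic
  zero — and extrapolated to zero. Non-crossing members (non-negative
  slope) are reported separately, never dropped. The ensemble SD is the
  spread across the four disturbance scenarios.

## Numerical choices and degenerate inputs

Annual explicit Euler throughout; exact-exponential product decay;
conservation tolerances 1e-9 relative per year, 1e-6 per run, 1e-12 for
tile area, 1e-15 for monthly disaggregation (the last month absorbs the
float rounding). Merging rounds the area-weighted age to the nearest
year. NaN forcing raises; burned + harvested fractions above available
area raise; all-zero monthly climatologies raise; CO₂ ≤ 0 raises.

## Problem sizes

Desk-scale defaults: 25 cells for domain runs, 8 cells for the
16-run factorial ensemble, 26 synthetic sites, 1000 replicates for the
trend type-I Monte Carlo, 1000 randomized years for the conservation
audit. These sizes were chosen so the whole pipeline reruns in well
under a minute per driver while keeping Monte-Carlo errors a few
percent.

## Known limitations

Single PFT per cell; no competition or dynamic vegetation; no
age-related productivity decline (see attribution note above); no
moisture limitation; products decay domestically (no trade fluxes); no
lateral/riverine carbon export; the national Tg analogues depend on the
nominal 400 Mha domain area and are structural, not geographic,
quantities.
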