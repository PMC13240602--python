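#!/usr/bin/env python
"""Twin-experiment site evaluation: run the factual/counterfactual
protocol at 26 synthetic chronosequence sites, score both variants
against noisy pseudo-tower observations, and tabulate delta-MAE by
years since disturbance.

Finding to look for: delta-MAE for NEP and AGB peaks at recently
disturbed sites and decays toward zero beyond ~50 yr — representing
disturbance only helps where its legacy is still in the fluxes."""

from pathlib import Path

from borealcarbon.site_eval import bin_chronosequence, twin_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    _, chrono = twin_experiment(seed=1)
    chrono.to_csv(OUT / "chronosequence.csv", index=False)
    binned = bin_chronosequence(chrono, bin_width=25.0)
    binned.to_csv(OUT / "chronosequence_binned.csv", index=False)
    for var in ("GPP", "ER", "NEP", "AGB"):
        sub = chrono[chrono.variable == var]
        young = sub[sub.years_since_disturbance < 20].delta_mae.mean()
        old = sub[sub.years_since_disturbance > 50].delta_mae.mean()
        print(f"{var:4s} delta-MAE: young (<20 yr) {young:8.3f}   "
              f"old (>50 yr) {old:8.3f}")
    print(f"wrote {OUT / 'chronosequence.csv'}")


if __name__ == "__main__":
    main()
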