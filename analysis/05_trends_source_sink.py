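#!/usr/bin/env python
"""Rolling 15-yr trend tests on the national NBP series and the
ensemble source-sink crossing estimate.

Reads the domain flux ledgers written by 03_domain_ensemble.py (runs it
first if needed), tests every 15-yr window from 1920 on for significant
negative trends, flags those that would flip the 10-yr running-mean
sign, and extrapolates each scenario's smoothed NBP trend to its zero
crossing."""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from borealcarbon.synthetic_data import DOMAIN_AREA_M2
from borealcarbon.trends import crossing_year, rolling_trend, \
    trend_results_frame

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
TG = DOMAIN_AREA_M2 / 1e9


def main() -> None:
    fluxes_path = OUT / "domain_fluxes.csv"
    if not fluxes_path.exists():
        subprocess.run([sys.executable,
                        str(ROOT / "analysis" / "03_domain_ensemble.py")],
                       check=True)
    df = pd.read_csv(fluxes_path)
    df = df[df.year >= 1920]

    ensemble = {}
    frames = []
    for name, sub in df.groupby("scenario"):
        years = sub.year.to_numpy()
        nbp = sub.nbp.to_numpy() * TG
        ensemble[name] = (years, nbp)
        res = rolling_trend(years, nbp, window=15)
        tf = trend_results_frame(res)
        tf.insert(0, "scenario", name)
        frames.append(tf)
        n_sig = int(tf.significant_negative.sum())
        n_flag = int(tf.flag_sign_change.sum())
        print(f"{name:16s} {n_sig:3d} significant negative 15-yr windows, "
              f"{n_flag:3d} would flip the running-mean sign")
    pd.concat(frames).to_csv(OUT / "trend_windows.csv", index=False)

    est = crossing_year(ensemble)
    print("\nsource-sink crossing estimate (10-yr running mean, 15-yr "
          "trend extrapolation):")
    for name, yr in est.member_years.items():
        print(f"  {name:16s} {yr:7.1f}")
    if est.non_crossing:
        print(f"  non-crossing members: {est.non_crossing}")
    if est.member_years:
        print(f"  ensemble mean {est.mean_year:.1f} "
              f"(SD {est.sd_years:.1f} yr)")
    pd.DataFrame(
        [{"member": k, "crossing_year": v}
         for k, v in est.member_years.items()]
        + [{"member": k, "crossing_year": float("nan")}
           for k in est.non_crossing]).to_csv(
        OUT / "crossing_years.csv", index=False)


if __name__ == "__main__":
    main()
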