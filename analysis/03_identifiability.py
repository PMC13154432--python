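#!/usr/bin/env python
"""Identifiability of the four-parameter transport model.

Aggregates the per-fit collinearity indices produced by 02_fit_cohort
and, at the reported primary-shoot parameter means, contrasts the two
sensitivity output surfaces: the compartment trajectories (the surface
a kinetic-modelling tool certifies, gamma ~ 10) versus the
frame-averaged ROI totals the objective actually sees (stricter).
Writes results/identifiability.csv.
"""

import json
from pathlib import Path

import pandas as pd

import phloempet as pp
from phloempet.model import PRIMARY_SHOOT_PARAMS

FITS = Path("results/fits/fits")
OUT = Path("results/identifiability.csv")


def main() -> None:
    rows = []
    for path in sorted(FITS.glob("*_fit.json")):
        fit = json.loads(path.read_text())
        ident = fit["identifiability"]
        full = "a12+b+c+s_ph"
        rows.append(
            {
                "set_id": path.stem.removesuffix("_fit"),
                "gamma_full": ident["gammas"][full],
                "identifiable": ident["identifiable"][full],
                "rmse": fit["rmse"],
            }
        )
    if not rows:
        raise SystemExit("no fits; run 02_fit_cohort.py first")
    df = pd.DataFrame(rows)
    df.to_csv(OUT, index=False)
    frac = df["identifiable"].mean()
    print(f"{len(df)} fits; full-set gamma median "
          f"{df['gamma_full'].median():.1f}, identifiable (gamma <= 15) in "
          f"{frac:.0%} of sets -> {OUT}")

    cfg = pp.SyntheticConfig(params=PRIMARY_SHOOT_PARAMS)
    noiseless, _, _ = pp.generate_roi_set(cfg)
    for surface in ("trajectories", "frames"):
        S = pp.relative_sensitivities(
            PRIMARY_SHOOT_PARAMS, cfg.geom, noiseless, output_surface=surface
        )
        g = pp.collinearity_index(S)
        print(f"gamma({{s_Ph,a12,b,c}}) on {surface:12s} surface at reported "
              f"primary means: {g:.1f}")
    print("the trajectory surface certifies the full set below the threshold "
          "of 15; the stricter frame surface shows one weakly constrained "
          "parameter combination (see docs/methods.md).")


if __name__ == "__main__":
    main()
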