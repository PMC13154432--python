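#!/usr/bin/env python
"""Calibrate every cohort ROI set by shuffled complex evolution.

Runs the full pipeline over the TAC files written by 01_simulate_cohort:
one independent four-parameter SCE-UA fit (h fixed at 0.68759) plus an
identifiability report per ROI set.  Writes fits and the tidy parameter
table under results/fits/ and prints recovery errors against the known
ground truths.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import phloempet as pp
from phloempet.pipeline import PipelineConfig, run_pipeline

COHORT = Path("results/cohort")
OUT = Path("results/fits")
GLOBAL_SEED = 20260920


def main() -> None:
    tac_files = tuple(
        (str(csv), str(csv.with_suffix(".yaml")))
        for csv in sorted(COHORT.glob("*.csv"))
    )
    if not tac_files:
        raise SystemExit("no cohort files; run 01_simulate_cohort.py first")
    run_dir = run_pipeline(
        PipelineConfig(output_dir=str(OUT), seed=GLOBAL_SEED, tac_files=tac_files)
    )
    table = pd.read_csv(run_dir / "parameters.csv")

    rows = []
    for _, row in table.iterrows():
        truth = json.loads((COHORT / f"{row.set_id}_truth.json").read_text())["params"]
        rows.append(
            {
                "set_id": row.set_id,
                **{
                    p: abs(row[p] - truth[p]) / truth[p] * 100
                    for p in ("s_ph", "a12", "b", "c")
                },
            }
        )
    err = pd.DataFrame(rows).set_index("set_id")
    err.round(1).to_csv(run_dir / "recovery_errors_pct.csv")
    print(f"fitted {len(table)} ROI sets -> {run_dir}/parameters.csv")
    print("\nrecovery error vs ground truth (%, median over sets):")
    print(err.median().round(1).to_string())
    print("\ns_Ph is recovered well from 5%-noise TACs; the three exchange")
    print("rates scatter widely -- at this noise level the data constrain")
    print("mainly their quasi-steady combinations (see docs/methods.md).")


if __name__ == "__main__":
    main()
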