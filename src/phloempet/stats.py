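"""Descriptive summaries of calibrated parameters across ROI sets.

Mean +/- standard error per shoot class, and plain (Pearson/Spearman)
correlations of parameters with position along the shoot.  Inferential
mixed-model testing is deliberately left to external statistics tooling
(plant individual enters as a random effect there); this module exports
the tidy per-fit table those tools consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

PARAM_COLUMNS = ("s_ph", "a12", "a21", "b", "c")
TIDY_COLUMNS = ("set_id", "plant_id", "shoot_class", "position_cm", *PARAM_COLUMNS)


def tidy_parameter_table(fits: list[dict]) -> pd.DataFrame:
    """Assemble the per-ROI-set parameter table from fit records.

    Each record needs ``set_id``, ``plant_id``, ``shoot_class``,
    optionally ``position_cm``, and a ``params`` dict with the five
    transport parameters (a21 = h * a12 is recomputed, never trusted).
    """
    rows = []
    for f in fits:
        p = f["params"]
        rows.append(
            {
                "set_id": f["set_id"],
                "plant_id": f["plant_id"],
                "shoot_class": f["shoot_class"],
                "position_cm": f.get("position_cm"),
                "s_ph": p["s_ph"],
                "a12": p["a12"],
                "a21": p["h"] * p["a12"],
                "b": p["b"],
                "c": p["c"],
            }
        )
    return pd.DataFrame(rows, columns=list(TIDY_COLUMNS))


def summarize_by_group(
    table: pd.DataFrame, parameter: str, group: str = "shoot_class"
) -> pd.DataFrame:
    """Arithmetic mean, standard error (sd / sqrt(n)) and n per group.

    Groups with fewer than two rows get ``se = NaN`` and are flagged.
    """
    if parameter not in table.columns:
        raise KeyError(f"unknown parameter column {parameter!r}")
    out = (
        table.groupby(group)[parameter]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["se_defined"] = out["n"] >= 2
    return out[[group, "mean", "se", "n", "se_defined"]]


def correlate_with_position(
    table: pd.DataFrame, parameter: str, method: str = "pearson"
) -> dict:
    """Correlation of a parameter with position along the shoot.

    Returns ``{"r": coefficient, "p": two-sided p-value, "n": pairs,
    "method": method}``.  A constant column has no defined correlation
    and raises ``ValueError``.
    """
    sub = table[["position_cm", parameter]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(sub)}")
    x = sub["position_cm"].to_numpy(float)
    y = sub[parameter].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant column")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": len(sub), "method": method}
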