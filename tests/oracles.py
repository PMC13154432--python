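"""Independent oracles for cross-checking the production code paths.

Everything here is written directly from the model equations and
standard formulas, deliberately avoiding the package's integrator,
optimizer and linear-algebra paths.
"""

from __future__ import annotations

import math

import numpy as np


def euler_simulate(s_ph, a12, b, c, h, roi_length_mm, time_min, input_vals,
                   dt_min: float = 0.001, t_end_min: float | None = None):
    """Fixed-step explicit-Euler integration of the four-compartment chain.

    ``time_min``/``input_vals`` define the measured input-ROI total
    (piecewise linear between frame midpoints, constant outside).
    Returns ``(t_min_grid, totals)`` where totals has one column per
    downstream ROI (ROIs 1-3), evaluated on the Euler grid.
    """
    k = s_ph / (1000.0 * roi_length_mm)
    a21 = h * a12
    tt = np.asarray(time_min) * 60.0
    tv = np.asarray(input_vals, dtype=float)
    t_end = (t_end_min if t_end_min is not None else time_min[-1] + 2.5) * 60.0
    dt = dt_min * 60.0
    n_steps = int(round(t_end / dt))
    y = np.zeros(11)
    out_t = np.empty(n_steps + 1)
    out = np.empty((n_steps + 1, 3))
    out_t[0] = 0.0
    out[0] = 0.0
    loss2 = a21 + b + c
    t = 0.0
    for step in range(1, n_steps + 1):
        tot = np.interp(t, tt, tv)
        c1_in = max(tot - y[0] - y[1], 0.0)
        d = np.empty(11)
        d[0] = a12 * c1_in - loss2 * y[0]
        d[1] = b * y[0]
        up = c1_in
        for j in range(3):
            base = 2 + 3 * j
            c1, c2 = y[base], y[base + 1]
            d[base] = k * up - k * c1 - a12 * c1 + a21 * c2
            d[base + 1] = a12 * c1 - loss2 * c2
            d[base + 2] = b * c2
            up = c1
        y = y + dt * d
        t = step * dt
        out_t[step] = t / 60.0
        for j in range(3):
            base = 2 + 3 * j
            out[step, j] = y[base] + y[base + 1] + y[base + 2]
    return out_t, out


def advection_cascade_closed_form(A, k, t_s, n_stages=3):
    """Step response of a linear advection cascade (a12 = 0).

    With constant upstream concentration ``A`` and identical stage rate
    ``k``, stage j (1-based) follows
    ``A * (1 - exp(-k t) * sum_{m<j} (k t)^m / m!)``.
    """
    t_s = np.asarray(t_s, dtype=float)
    out = np.empty((t_s.size, n_stages))
    for j in range(1, n_stages + 1):
        partial = sum((k * t_s) ** m / math.factorial(m) for m in range(j))
        out[:, j - 1] = A * (1.0 - np.exp(-k * t_s) * partial)
    return out


def gamma_via_svd(matrix: np.ndarray) -> float:
    """Collinearity index via singular values of the normalized columns."""
    M = np.asarray(matrix, dtype=float)
    Mn = M / np.linalg.norm(M, axis=0)
    smin = np.linalg.svd(Mn, compute_uv=False)[-1]
    return 1.0 / smin


def spearman_brute(x, y):
    """Rank correlation from first principles (average ranks for ties)."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(v.size)
        i = 0
        sorted_v = v[order]
        while i < v.size:
            j = i
            while j + 1 < v.size and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
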