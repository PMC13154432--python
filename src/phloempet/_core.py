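"""Compiled integration kernel for the four-compartment ROI chain.

The model state is packed into a flat vector so the whole right-hand side
and the adaptive Cash-Karp Runge-Kutta 4(5) stepper can run inside a single
numba-compiled loop.  Layout of the 18-element state vector (all
concentrations in MBq mL^-1, time in seconds):

    0      C2 of the input ROI (transient storage)
    1      C3 of the input ROI (immobile storage)
    2+3j   C1 of downstream ROI j   (j = 0, 1, 2)
    3+3j   C2 of downstream ROI j
    4+3j   C3 of downstream ROI j
    11+j   running integral of the total concentration of ROI j
    14     running integral of the advective inflow  k * C1_input
    15     running integral of the atmospheric efflux c * (C2_1 + C2_2 + C2_3)
    16     running integral of the advective outflow k * C1_3
    17     running integral of the input-ROI total concentration

C1 of the input ROI is algebraic: it is the measured total minus the two
simulated storage pools, floored at zero.  The running integrals make
frame-averaged outputs and the mass-balance audit exact by-products of the
integration (divided differences at frame edges) instead of quadrature over
a recorded grid.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATE = 18

# Cash-Karp 4(5) tableau
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 3.0 / 10.0, -9.0 / 10.0, 6.0 / 5.0
_A51, _A52, _A53, _A54 = -11.0 / 54.0, 5.0 / 2.0, -70.0 / 27.0, 35.0 / 27.0
_A61, _A62, _A63, _A64, _A65 = (
    1631.0 / 55296.0,
    175.0 / 512.0,
    575.0 / 13824.0,
    44275.0 / 110592.0,
    253.0 / 4096.0,
)
_C2, _C3, _C4, _C5, _C6 = 1.0 / 5.0, 3.0 / 10.0, 3.0 / 5.0, 1.0, 7.0 / 8.0
# 5th order weights
_B1, _B3, _B4, _B6 = 37.0 / 378.0, 250.0 / 621.0, 125.0 / 594.0, 512.0 / 1771.0
# 4th order weights
_D1, _D3, _D4, _D5, _D6 = (
    2825.0 / 27648.0,
    18575.0 / 48384.0,
    13525.0 / 55296.0,
    277.0 / 14336.0,
    1.0 / 4.0,
)


@njit(cache=True)
def interp_input(t, tt, tv):
    """Piecewise-linear interpolant of the measured input-ROI total.

    Constant extrapolation before the first and after the last node
    (nodes are frame midpoints).
    """
    n = tt.shape[0]
    if t <= tt[0]:
        return tv[0]
    if t >= tt[n - 1]:
        return tv[n - 1]
    i = np.searchsorted(tt, t) - 1
    w = (t - tt[i]) / (tt[i + 1] - tt[i])
    return tv[i] * (1.0 - w) + tv[i + 1] * w


@njit(cache=True)
def rhs(t, y, out, k, a12, a21, b, c, tt, tv):
    tot = interp_input(t, tt, tv)
    c1_in = tot - y[0] - y[1]
    if c1_in < 0.0:
        c1_in = 0.0
    loss2 = a21 + b + c
    out[0] = a12 * c1_in - loss2 * y[0]
    out[1] = b * y[0]
    up = c1_in
    for j in range(3):
        base = 2 + 3 * j
        c1 = y[base]
        c2 = y[base + 1]
        out[base] = k * up - k * c1 - a12 * c1 + a21 * c2
        out[base + 1] = a12 * c1 - loss2 * c2
        out[base + 2] = b * c2
        out[11 + j] = c1 + c2 + y[base + 2]
        up = c1
    out[14] = k * c1_in
    out[15] = c * (y[3] + y[6] + y[9])
    out[16] = k * y[8]
    out[17] = c1_in + y[0] + y[1]


@njit(cache=True)
def integrate(y0, t_out, rtol, atol, max_step, k, a12, a21, b, c, tt, tv):
    """Adaptive Cash-Karp RK4(5) from t_out[0] through every output time.

    Returns (ys, status, t_fail): ys[i] is the state at t_out[i]; status 0
    on success, 1 if the step size underflowed (t_fail = last valid time).
    """
    n_out = t_out.shape[0]
    ys = np.empty((n_out, N_STATE))
    y = y0.copy()
    ys[0] = y
    t = t_out[0]
    span = t_out[n_out - 1] - t_out[0]
    h_min = 1e-12 * span + 1e-15
    h = max_step

    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    k5 = np.empty(N_STATE)
    k6 = np.empty(N_STATE)
    ytmp = np.empty(N_STATE)
    y5 = np.empty(N_STATE)
    y4 = np.empty(N_STATE)

    for i in range(1, n_out):
        t_end = t_out[i]
        while t < t_end - 1e-10:
            if h > t_end - t:
                h = t_end - t
            if h > max_step:
                h = max_step
            rhs(t, y, k1, k, a12, a21, b, c, tt, tv)
            for m in range(N_STATE):
                ytmp[m] = y[m] + h * _A21 * k1[m]
            rhs(t + _C2 * h, ytmp, k2, k, a12, a21, b, c, tt, tv)
            for m in range(N_STATE):
                ytmp[m] = y[m] + h * (_A31 * k1[m] + _A32 * k2[m])
            rhs(t + _C3 * h, ytmp, k3, k, a12, a21, b, c, tt, tv)
            for m in range(N_STATE):
                ytmp[m] = y[m] + h * (_A41 * k1[m] + _A42 * k2[m] + _A43 * k3[m])
            rhs(t + _C4 * h, ytmp, k4, k, a12, a21, b, c, tt, tv)
            for m in range(N_STATE):
                ytmp[m] = y[m] + h * (
                    _A51 * k1[m] + _A52 * k2[m] + _A53 * k3[m] + _A54 * k4[m]
                )
            rhs(t + _C5 * h, ytmp, k5, k, a12, a21, b, c, tt, tv)
            for m in range(N_STATE):
                ytmp[m] = y[m] + h * (
                    _A61 * k1[m]
                    + _A62 * k2[m]
                    + _A63 * k3[m]
                    + _A64 * k4[m]
                    + _A65 * k5[m]
                )
            rhs(t + _C6 * h, ytmp, k6, k, a12, a21, b, c, tt, tv)

            err_norm = 0.0
            for m in range(N_STATE):
                y5[m] = y[m] + h * (
                    _B1 * k1[m] + _B3 * k3[m] + _B4 * k4[m] + _B6 * k6[m]
                )
                y4[m] = y[m] + h * (
                    _D1 * k1[m]
                    + _D3 * k3[m]
                    + _D4 * k4[m]
                    + _D5 * k5[m]
                    + _D6 * k6[m]
                )
                ay = abs(y[m])
                ay5 = abs(y5[m])
                sk = atol + rtol * (ay if ay > ay5 else ay5)
                e = abs(y5[m] - y4[m]) / sk
                if e > err_norm:
                    err_norm = e

            if err_norm <= 1.0:
                t += h
                for m in range(N_STATE):
                    v = y5[m]
                    # concentrations cannot go negative; clip RK undershoot
                    if m < 11 and v < 0.0:
                        v = 0.0
                    y[m] = v
                if err_norm < 1e-10:
                    fac = 5.0
                else:
                    fac = 0.9 * err_norm ** (-0.2)
                    if fac > 5.0:
                        fac = 5.0
                h = h * fac
            else:
                fac = 0.9 * err_norm ** (-0.2)
                if fac < 0.2:
                    fac = 0.2
                h = h * fac
                if h < h_min:
                    for r in range(i, n_out):
                        ys[r] = y
                    return ys, 1, t
        ys[i] = y
    return ys, 0, t
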