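"""Four-compartment kinetic model of phloem tracer transport in a shoot.

Each cylindrical ROI along the shoot is split into four pools: (1) the
sieve-element/companion-cell transport pathway, (2) a transient storage
pool (phloem parenchyma) that exchanges with the pathway, (3) an
irreversible storage pool (phloem cap), and (4) the atmosphere, reached
by respiratory efflux.  With ``k = s_Ph / l`` the advective rate
constant, the concentrations (MBq mL^-1) of ROI ``i`` obey::

    dC1_i/dt = k*C1_{i-1} - k*C1_i - a12*C1_i + a21*C2_i
    dC2_i/dt = a12*C1_i - a21*C2_i - b*C2_i - c*C2_i
    dC3_i/dt = b*C2_i

where ``a21 = h * a12`` (fixed coupling, h = 0.68759 by default).  The
most proximal (input) ROI is forced by measurement: its transport-pool
concentration is the measured total minus the two simulated storage
pools, floored at zero; its storage pools evolve by the same equations.

Units: parameters are quoted in field units (``s_Ph`` in µm s^-1,
``l`` in mm, exchange rates in s^-1, TAC times in minutes); all
internal integration is in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _core
from .tac import ROI_COLUMNS, RoiGeometry, TacTable

logger = logging.getLogger(__name__)

H_DEFAULT = 0.68759  # coupling constant a21 = h * a12 (mean of identifiable fits)


class SimulationError(RuntimeError):
    """Integrator failure; carries the last time reached."""

    def __init__(self, message: str, t_last_s: float):
        super().__init__(message)
        self.t_last_s = t_last_s


@dataclass(frozen=True)
class ModelParameters:
    """Transport parameters of one ROI set.

    s_ph : phloem front speed, µm s^-1 (plug flow, > 0)
    a12  : unloading rate from the transport pathway, s^-1, in [0, 1]
    b    : storage (immobilization) rate, s^-1, in [0, 1]
    c    : atmospheric efflux rate, s^-1, in [0, 1]
    h    : dimensionless retrieval coupling in (0, 1]; a21 = h * a12
           is always derived, never set independently.
    """

    s_ph: float
    a12: float
    b: float
    c: float
    h: float = H_DEFAULT

    def __post_init__(self) -> None:
        if self.s_ph <= 0:
            raise ValueError(f"s_ph must be > 0 µm/s, got {self.s_ph}")
        for name in ("a12", "b", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1] s^-1, got {v}")
        if not 0.0 < self.h <= 1.0:
            raise ValueError(f"h must lie in (0, 1], got {self.h}")

    @property
    def a21(self) -> float:
        return self.h * self.a12

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "s_ph": self.s_ph,
            "a12": self.a12,
            "b": self.b,
            "c": self.c,
            "h": self.h,
            "a21": self.a21,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(
            s_ph=float(d["s_ph"]),
            a12=float(d["a12"]),
            b=float(d["b"]),
            c=float(d["c"]),
            h=float(d.get("h", H_DEFAULT)),
        )


#: Mean transport parameters by shoot class.  The quoted exchange-rate
#: magnitudes (0.27 / 0.08 / 0.38 primary, 0.07 / 0.25 / 0.30 secondary)
#: are per-minute rates, converted here to s^-1: taken literally as
#: s^-1 they would empty the transport pool within seconds, attenuate
#: TACs several-fold per ROI and make the parameter set structurally
#: unidentifiable at 5-min frames, contradicting the observed mildly
#: decreasing TACs and the identifiability of the fits.
PRIMARY_SHOOT_PARAMS = ModelParameters(
    s_ph=128.0, a12=0.27 / 60.0, b=0.08 / 60.0, c=0.38 / 60.0
)
SECONDARY_SHOOT_PARAMS = ModelParameters(
    s_ph=70.0, a12=0.07 / 60.0, b=0.25 / 60.0, c=0.30 / 60.0
)


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings (defaults: tolerance 1e-5, max step 0.01 min)."""

    rtol: float = 1e-5
    atol: float = 1e-10
    max_step_min: float = 0.01
    dense_dt_min: float = 0.1
    frame_aggregation: str = "mean"  # "mean" (frame average) or "midpoint"
    init_mode: str = "compartment1"  # or "distributed"

    def __post_init__(self) -> None:
        if self.frame_aggregation not in ("mean", "midpoint"):
            raise ValueError(f"unknown frame_aggregation {self.frame_aggregation!r}")
        if self.init_mode not in ("compartment1", "distributed"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Dense trajectories plus per-frame aggregates of one forward run.

    ``conc[roi][comp]`` with roi in {"input","roi1","roi2","roi3"} and
    comp in {"C1","C2","C3"} are trajectories on ``t_min``;
    ``totals`` is (n_t, 4) and ``frame_totals`` (n_frames, 4) in the
    same column order.  Cumulative advective inflow into ROI 1,
    atmospheric efflux from ROIs 1-3 and advective outflow from ROI 3
    (MBq mL^-1 equivalents) support the mass-balance audit.
    """

    t_min: np.ndarray
    conc: dict
    totals: np.ndarray
    frame_time_min: np.ndarray
    frame_totals: np.ndarray
    cumulative_inflow: float
    cumulative_efflux: float
    cumulative_outflow: float
    params: ModelParameters
    geom: RoiGeometry
    solver: SolverConfig

    def frame_table(self, decay_corrected: bool = True) -> TacTable:
        width = float(np.median(np.diff(self.frame_time_min))) if self.frame_time_min.size > 1 else 5.0
        return TacTable(self.frame_time_min, self.frame_totals, width, decay_corrected)


def advective_rate_constant(params: ModelParameters, geom: RoiGeometry) -> float:
    """Advective rate ``k = s_Ph / l`` in s^-1.

    ``s_Ph`` is in µm s^-1 and ``l`` in mm, so k = s_ph / (1000 * l).
    """
    if geom.roi_length_mm <= 0:
        raise ValueError("ROI length must be positive")
    if params.s_ph <= 0:
        raise ValueError("s_ph must be positive")
    return params.s_ph / (1000.0 * geom.roi_length_mm)


def input_c1(total_measured: float, c2_in: float, c3_in: float) -> float:
    """Transport-pool concentration of the input ROI (closure relation).

    Returns ``total - C2 - C3`` floored at zero; under measurement noise
    the simulated storage pools can transiently exceed the measured
    total, in which case the floor applies.
    """
    v = total_measured - c2_in - c3_in
    if v < 0.0:
        logger.debug("input C1 floored at 0 (total=%g, C2+C3=%g)", total_measured, c2_in + c3_in)
        return 0.0
    return v


def derivatives(t_s: float, state: np.ndarray, params: ModelParameters,
                geom: RoiGeometry, input_total) -> np.ndarray:
    """Time derivative of the 11-element compartment state (reference path).

    ``state`` is [C2_in, C3_in, C1_1, C2_1, C3_1, ..., C3_3];
    ``input_total(t_s)`` returns the measured input-ROI total at time
    ``t_s`` (seconds).  This pure-Python implementation mirrors the
    compiled kernel and is the inspectable reference for single-point
    evaluation.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (11,):
        raise ValueError(f"state must have shape (11,), got {state.shape}")
    k = advective_rate_constant(params, geom)
    a12, a21, b, c = params.a12, params.a21, params.b, params.c
    c1_in = input_c1(float(input_total(t_s)), state[0], state[1])
    d = np.empty(11)
    loss2 = a21 + b + c
    d[0] = a12 * c1_in - loss2 * state[0]
    d[1] = b * state[0]
    up = c1_in
    for j in range(3):
        base = 2 + 3 * j
        c1, c2 = state[base], state[base + 1]
        d[base] = k * up - k * c1 - a12 * c1 + a21 * c2
        d[base + 1] = a12 * c1 - loss2 * c2
        d[base + 2] = b * c2
        up = c1
    return d


def input_interpolant(tac: TacTable):
    """Piecewise-linear interpolant (time in s) of the measured input
    total, constant beyond the first/last frame midpoint."""
    tt = tac.time_min * 60.0
    tv = tac.input.copy()

    def f(t_s: float) -> float:
        return float(np.interp(t_s, tt, tv))

    return f


def _initial_state(tac: TacTable, solver: SolverConfig) -> np.ndarray:
    y0 = np.zeros(_core.N_STATE)
    if solver.init_mode == "distributed":
        # spread the first-frame activity evenly over the three input pools
        tot0 = tac.input[0]
        y0[0] = tot0 / 3.0
        y0[1] = tot0 / 3.0
    return y0


def simulate(
    params: ModelParameters,
    geom: RoiGeometry,
    input_tac: TacTable,
    solver: SolverConfig | None = None,
    dense: bool = True,
) -> SimulationResult:
    """Forward-simulate the ROI chain driven by the measured input TAC.

    Integration starts at the first frame edge (t = 0) with all
    first-frame activity in the transport pool of the input ROI (or
    distributed over its pools, see ``SolverConfig.init_mode``) and all
    downstream pools empty.  ``frame_totals`` are exact frame averages
    (from running integrals) or midpoint samples, per
    ``SolverConfig.frame_aggregation``.  With ``dense=False`` only frame
    aggregates are computed (fast path used by calibration).
    """
    solver = solver or SolverConfig()
    if not input_tac.decay_corrected:
        raise ValueError("model requires decay-corrected TACs (it has no decay term)")
    k = advective_rate_constant(params, geom)
    tt = input_tac.time_min * 60.0
    tv = np.ascontiguousarray(input_tac.input)
    edges_s = input_tac.frame_edges_min * 60.0
    mids_s = input_tac.time_min * 60.0

    if solver.frame_aggregation == "midpoint":
        frame_nodes = np.concatenate([[edges_s[0]], mids_s, [edges_s[-1]]])
    else:
        frame_nodes = edges_s
    if dense:
        t_out = np.arange(edges_s[0], edges_s[-1] + 1e-9, solver.dense_dt_min * 60.0)
        t_out = np.unique(np.concatenate([t_out, frame_nodes]))
    else:
        t_out = frame_nodes
    node_idx = np.searchsorted(t_out, frame_nodes)

    y0 = _initial_state(input_tac, solver)
    ys, status, t_fail = _core.integrate(
        y0, t_out, solver.rtol, solver.atol, solver.max_step_min * 60.0,
        k, params.a12, params.a21, params.b, params.c, tt, tv,
    )
    if status != 0:
        raise SimulationError(
            f"step size underflow at t = {t_fail / 60.0:.3f} min", t_fail
        )

    tot_in_meas = np.interp(t_out, tt, tv)
    c1_in = np.maximum(tot_in_meas - ys[:, 0] - ys[:, 1], 0.0)
    conc = {"input": {"C1": c1_in, "C2": ys[:, 0], "C3": ys[:, 1]}}
    totals = np.empty((t_out.size, 4))
    totals[:, 0] = c1_in + ys[:, 0] + ys[:, 1]
    for j, name in enumerate(ROI_COLUMNS[1:]):
        base = 2 + 3 * j
        conc[name] = {"C1": ys[:, base], "C2": ys[:, base + 1], "C3": ys[:, base + 2]}
        totals[:, j + 1] = ys[:, base] + ys[:, base + 1] + ys[:, base + 2]

    n_frames = input_tac.n_frames
    frame_totals = np.empty((n_frames, 4))
    if solver.frame_aggregation == "mean":
        width_s = np.diff(edges_s)
        at_edges = ys[node_idx]
        # ROI 1-3 averages from running integrals; input from its own integral
        for j in range(3):
            frame_totals[:, j + 1] = np.diff(at_edges[:, 11 + j]) / width_s
        frame_totals[:, 0] = np.diff(at_edges[:, 17]) / width_s
    else:
        frame_totals[:, :] = totals[node_idx[1:-1]]

    y_end = ys[-1]
    return SimulationResult(
        t_min=t_out / 60.0,
        conc=conc,
        totals=totals,
        frame_time_min=input_tac.time_min.copy(),
        frame_totals=frame_totals,
        cumulative_inflow=float(y_end[14]),
        cumulative_efflux=float(y_end[15]),
        cumulative_outflow=float(y_end[16]),
        params=params,
        geom=geom,
        solver=solver,
    )


def mass_balance(result: SimulationResult) -> float:
    """Conservation audit of the ROI chain (dimensionless residual).

    Everything advected into ROI 1 must at the end of the run be stored
    in ROIs 1-3, have effluxed to the atmosphere, or have been advected
    out of ROI 3:

        |stored + efflux + outflow - inflow| / inflow

    Zero inflow returns 0 by convention.
    """
    stored = float(result.totals[-1, 1:].sum())
    inflow = result.cumulative_inflow
    if inflow == 0.0:
        return 0.0
    return abs(stored + result.cumulative_efflux + result.cumulative_outflow - inflow) / inflow
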