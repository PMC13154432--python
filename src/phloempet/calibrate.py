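"""Per-ROI-set parameter estimation by SCE-UA over the TAC RMSE.

One ROI set (one TAC table) yields one independent fit of
{s_Ph, a12, b, c} (optionally + h).  The objective is the root mean
square error between simulated and measured frame totals of the three
downstream ROIs; the input ROI is forcing, not data.  The paper-mode
configuration uses nine complexes (2 x 4 + 1), convergence accuracy
1e-5 and a budget of 4500 objective evaluations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    H_DEFAULT,
    ModelParameters,
    SimulationError,
    SolverConfig,
    simulate,
)
from .optimize import sce_minimize
from .tac import RoiGeometry, TacTable

logger = logging.getLogger(__name__)

PARAM_ORDER = ("s_ph", "a12", "b", "c", "h")

#: Default search box.  s_Ph brackets the observed 32-216 µm/s with
#: margin; the exchange rates bracket the observed 0.0012-0.0075 s^-1
#: with a ~10x margin.  The full theoretical [0, 1] s^-1 range contains
#: a spurious quasi-static basin at ~60x faster rates (indistinguishable
#: at 5-min frames to ~0.02% of signal) that a global search can fall
#: into; widen the box explicitly if such rates are plausible.
DEFAULT_BOUNDS = {
    "s_ph": (1.0, 500.0),   # µm s^-1
    "a12": (0.0, 0.05),     # s^-1
    "b": (0.0, 0.05),       # s^-1
    "c": (0.0, 0.05),       # s^-1
    "h": (1e-6, 1.0),       # dimensionless
}

PENALTY_SCALE = 1e6  # solver-failure objective = PENALTY_SCALE * data scale


@dataclass(frozen=True)
class CalibrationConfig:
    free_parameters: tuple = ("s_ph", "a12", "b", "c")
    n_complexes: int | None = None  # default 2 * n_free + 1
    # nine complexes need ~10k objective calls to meet the 1e-5 accuracy
    # criterion on clean data; the criterion, not the budget, should stop
    # a healthy fit
    max_evaluations: int = 12000
    accuracy: float = 1e-5
    k_loops: int = 5
    bounds: dict = field(default_factory=dict)  # overrides of DEFAULT_BOUNDS
    seed: int = 0
    h_fixed: float = H_DEFAULT
    # error control (rtol 1e-5) makes the forward-simulation step cap
    # redundant inside the objective; the relaxed cap is ~10x faster and
    # agrees with the capped solver to ~1e-9 relative
    solver: SolverConfig = field(default_factory=lambda: SolverConfig(max_step_min=0.5))

    def __post_init__(self) -> None:
        unknown = set(self.free_parameters) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown free parameter(s) {sorted(unknown)}")
        if self.n_complexes is not None and self.n_complexes < 2:
            raise ValueError("n_complexes must be >= 2")
        for name, (bl, bu) in self.bounds.items():
            if not (np.isfinite(bl) and np.isfinite(bu)):
                raise ValueError(f"bounds for {name} must be finite")
            if name in ("a12", "b", "c") and not (0 <= bl < bu <= 1):
                raise ValueError(f"{name} bounds must lie within [0, 1] s^-1")

    @property
    def effective_n_complexes(self) -> int:
        return self.n_complexes if self.n_complexes is not None else 2 * len(self.free_parameters) + 1

    def bound(self, name: str):
        return self.bounds.get(name, DEFAULT_BOUNDS[name])

    def to_dict(self) -> dict:
        return {
            "free_parameters": list(self.free_parameters),
            "n_complexes": self.effective_n_complexes,
            "max_evaluations": self.max_evaluations,
            "accuracy": self.accuracy,
            "k_loops": self.k_loops,
            "bounds": {p: list(self.bound(p)) for p in self.free_parameters},
            "seed": self.seed,
            "h_fixed": self.h_fixed,
        }


@dataclass(frozen=True)
class CalibrationResult:
    params: ModelParameters
    rmse: float
    n_evaluations: int
    converged: bool
    seed: int
    config: CalibrationConfig
    residuals: np.ndarray  # (n_frames, 3) simulated - observed, ROIs 1-3
    identifiability: object | None = None

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "rmse": self.rmse,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }
        if self.identifiability is not None:
            d["identifiability"] = self.identifiability.to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _build_params(x: np.ndarray, free: tuple, cfg: CalibrationConfig) -> ModelParameters:
    d = dict(zip(free, x))
    return ModelParameters(
        s_ph=d.get("s_ph", DEFAULT_BOUNDS["s_ph"][0]),
        a12=d.get("a12", 0.0),
        b=d.get("b", 0.0),
        c=d.get("c", 0.0),
        h=d.get("h", cfg.h_fixed),
    )


def rmse_objective(
    params: ModelParameters,
    observed: TacTable,
    geom: RoiGeometry,
    solver: SolverConfig | None = None,
) -> float:
    """RMSE (MBq mL^-1) between simulated and measured frame totals.

    Pools all frames of ROIs 1-3 with equal weight; the input ROI is
    excluded.  A solver failure returns a large penalty proportional to
    the data scale so a global search can continue past a pathological
    parameter vector.
    """
    try:
        sim = simulate(params, geom, observed, solver=solver, dense=False)
    except SimulationError as exc:
        logger.warning("solver failure during objective (%s); penalty applied", exc)
        return PENALTY_SCALE * max(float(np.abs(observed.values).max()), 1e-30)
    resid = sim.frame_totals[:, 1:] - observed.rois
    return float(np.sqrt(np.mean(resid**2)))


def calibrate(
    observed: TacTable,
    geom: RoiGeometry,
    cfg: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Fit the free parameters of one ROI set by SCE-UA.

    Deterministic for a fixed ``cfg.seed``.  If the evaluation budget is
    exhausted before the accuracy criterion is met the result is
    returned with ``converged=False`` rather than raising.
    """
    cfg = cfg or CalibrationConfig()
    if observed.n_frames < 8:
        raise ValueError(f"need at least 8 frames to calibrate, got {observed.n_frames}")
    free = tuple(cfg.free_parameters)
    bounds = [cfg.bound(p) for p in free]

    def objective(x):
        try:
            params = _build_params(x, free, cfg)
        except ValueError:
            return PENALTY_SCALE * max(float(np.abs(observed.values).max()), 1e-30)
        return rmse_objective(params, observed, geom, cfg.solver)

    res = sce_minimize(
        objective,
        bounds,
        seed=cfg.seed,
        n_complexes=cfg.effective_n_complexes,
        max_evaluations=cfg.max_evaluations,
        accuracy=cfg.accuracy,
        k_loops=cfg.k_loops,
    )
    params = _build_params(res.x, free, cfg)
    sim = simulate(params, geom, observed, solver=cfg.solver, dense=False)
    residuals = sim.frame_totals[:, 1:] - observed.rois
    return CalibrationResult(
        params=params,
        rmse=res.fun,
        n_evaluations=res.nfev,
        converged=res.converged,
        seed=cfg.seed,
        config=cfg,
        residuals=residuals,
    )


def calibrate_five_param(
    observed: TacTable,
    geom: RoiGeometry,
    cfg: CalibrationConfig | None = None,
) -> CalibrationResult:
    """Fit the five-parameter model {s_Ph, a12, b, c, h}.

    Used together with the identifiability module to decide, per ROI
    set, whether h is identifiable; the coupling constant is then fixed
    to the average of h over the identifiable fits (see
    :func:`average_h`).  The default evaluation budget is larger than
    for the four-parameter fit: the extra h direction is weakly
    identified and convergence takes ~30k objective calls.
    """
    cfg = cfg or CalibrationConfig(max_evaluations=30000)
    if "h" not in cfg.free_parameters:
        cfg = replace(cfg, free_parameters=(*cfg.free_parameters, "h"))
    return calibrate(observed, geom, cfg)


def average_h(values, ndigits: int = 4) -> float:
    """Mean of calibrated h values (CalibrationResults or floats),
    reported to ``ndigits`` decimals."""
    hs = [v.params.h if isinstance(v, CalibrationResult) else float(v) for v in values]
    if not hs:
        raise ValueError("no h values to average")
    return round(float(np.mean(hs)), ndigits)
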