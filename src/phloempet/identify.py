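"""Local sensitivity analysis and collinearity-index identifiability.

Relative (log-scaled) parameter sensitivities of the model outputs are
estimated by central finite differences; a parameter subset is deemed
identifiable when the collinearity index of its unit-normalized
sensitivity columns,

    gamma = 1 / sqrt(lambda_min(S~' S~)),

stays below a threshold (15 by convention): a large gamma means some
linear combination of the subset's columns is nearly zero, i.e. the
parameters can compensate each other on those outputs.

Two output surfaces are supported.  ``"trajectories"`` (default) takes
the simulated compartment concentrations of the downstream ROIs on a
dense grid -- the surface a kinetic-modelling tool reports and the one
on which the published 5-10 range of gamma values is reproduced.
``"frames"`` restricts to the frame-averaged ROI totals, exactly what
the calibration objective can see; it is the stricter criterion (a
gamma can be acceptable on trajectories yet large on frames when
distinct internal dynamics produce near-identical frame totals) and is
the right surface for asking whether the *data* can resolve a subset.
Rows are scaled by the measurement-error model sd = cv*y + floor, the
canonical scale-factor choice for collinearity analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .calibrate import DEFAULT_BOUNDS
from .model import ModelParameters, SolverConfig, simulate
from .tac import RoiGeometry, TacTable

GAMMA_THRESHOLD = 15.0

#: solver tolerance for sensitivity runs; central differences with a
#: 1e-4 relative step need trajectories resolved well below that scale
_SENS_RTOL = 1e-9


@dataclass(frozen=True)
class SensitivityMatrix:
    """Relative sensitivities d y / d ln(theta), row-scaled.

    ``matrix`` has one row per output point and one column per
    parameter in ``parameter_names``; ``normalization`` records the
    row scaling applied (for auditability across conventions).
    """

    matrix: np.ndarray
    parameter_names: tuple
    point_labels: tuple
    rel_perturbation: float
    output_surface: str
    normalization: str

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.parameter_names.index(name)]


@dataclass(frozen=True)
class IdentifiabilityReport:
    gammas: dict  # subset (tuple of names) -> gamma
    threshold: float
    parameter_names: tuple
    output_surface: str
    normalization: str

    @property
    def identifiable(self) -> dict:
        return {s: g <= self.threshold for s, g in self.gammas.items()}

    def gamma(self, *names) -> float:
        return self.gammas[tuple(sorted(names))]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "output_surface": self.output_surface,
            "normalization": self.normalization,
            "gammas": {"+".join(s): (g if np.isfinite(g) else "inf") for s, g in self.gammas.items()},
            "identifiable": {"+".join(s): bool(v) for s, v in self.identifiable.items()},
        }


def relative_sensitivities(
    params: ModelParameters,
    geom: RoiGeometry,
    input_tac: TacTable,
    free: tuple = ("s_ph", "a12", "b", "c"),
    rel_perturbation: float = 1e-4,
    output_surface: str = "trajectories",
    noise_cv: float = 0.05,
    noise_floor: float = 0.001,
    solver: SolverConfig | None = None,
) -> SensitivityMatrix:
    """Central-difference relative sensitivities of the model outputs.

    Each column is ``theta * d y / d theta`` with rows divided by the
    measurement-error scale ``noise_cv * |y| + noise_floor``.  The step
    is ``rel_perturbation`` times the parameter value with an absolute
    floor of 1e-8; a parameter sitting on a bound falls back to a
    one-sided difference (with a warning).
    """
    if output_surface not in ("trajectories", "frames"):
        raise ValueError(f"unknown output_surface {output_surface!r}")
    solver = solver or SolverConfig(max_step_min=0.5, dense_dt_min=2.5)
    solver = dc_replace(solver, rtol=min(solver.rtol, _SENS_RTOL))
    dense = output_surface == "trajectories"
    rois = ("roi1", "roi2", "roi3")

    def outputs(p: ModelParameters) -> np.ndarray:
        sim = simulate(p, geom, input_tac, solver=solver, dense=dense)
        if dense:
            return np.concatenate(
                [sim.conc[r][c] for r in rois for c in ("C1", "C2", "C3")]
            )
        return sim.frame_totals[:, 1:].ravel()

    y0 = outputs(params)
    scale = noise_cv * np.abs(y0) + noise_floor
    cols = []
    for name in free:
        theta = getattr(params, name)
        step = max(rel_perturbation * abs(theta), 1e-8)
        lo, hi = DEFAULT_BOUNDS[name]
        up, down = theta + step, theta - step
        if down < lo and up > hi:
            raise ValueError(f"cannot perturb {name}: bounds too tight for step {step}")
        if down < lo:
            warnings.warn(f"{name} on lower bound; using one-sided (forward) difference")
            deriv = (outputs(params.replace(**{name: up})) - y0) / step
        elif up > hi:
            warnings.warn(f"{name} on upper bound; using one-sided (backward) difference")
            deriv = (y0 - outputs(params.replace(**{name: down}))) / step
        else:
            deriv = (
                outputs(params.replace(**{name: up}))
                - outputs(params.replace(**{name: down}))
            ) / (2.0 * step)
        cols.append(theta * deriv / scale)

    if dense:
        n_t = y0.size // 9
        labels = tuple(
            (r, c, i) for r in rois for c in ("C1", "C2", "C3") for i in range(n_t)
        )
    else:
        labels = tuple(
            (f, r) for f in range(input_tac.n_frames) for r in rois
        )
    return SensitivityMatrix(
        matrix=np.column_stack(cols),
        parameter_names=tuple(free),
        point_labels=labels,
        rel_perturbation=rel_perturbation,
        output_surface=output_surface,
        normalization=(
            f"theta * dy/dtheta / (cv*|y| + floor), cv={noise_cv}, "
            f"floor={noise_floor}; columns unit-normalized for gamma"
        ),
    )


def collinearity_index(S: SensitivityMatrix | np.ndarray, subset=None) -> float:
    """Collinearity index of a parameter subset.

    ``gamma = 1 / sqrt(lambda_min)`` of the Gram matrix of the subset's
    unit-normalized columns.  Size-1 subsets return 1 by convention;
    exactly collinear (or zero) columns return ``inf``.
    """
    if isinstance(S, SensitivityMatrix):
        if subset is None:
            subset = S.parameter_names
        idx = [S.parameter_names.index(p) for p in subset]
        M = S.matrix[:, idx]
    else:
        M = np.asarray(S, dtype=float)
        if subset is not None:
            M = M[:, list(subset)]
    if M.ndim != 2 or M.shape[1] == 0:
        raise ValueError("subset must be non-empty")
    norms = np.linalg.norm(M, axis=0)
    if np.any(norms == 0.0):
        return np.inf
    Mn = M / norms
    if Mn.shape[1] == 1:
        return 1.0
    lam_min = float(np.linalg.eigvalsh(Mn.T @ Mn)[0])
    if lam_min <= 1e-12:
        return np.inf
    return 1.0 / np.sqrt(lam_min)


def assess(
    params: ModelParameters,
    geom: RoiGeometry,
    input_tac: TacTable,
    free: tuple = ("s_ph", "a12", "b", "c"),
    threshold: float = GAMMA_THRESHOLD,
    rel_perturbation: float = 1e-4,
    output_surface: str = "trajectories",
    sensitivities: SensitivityMatrix | None = None,
) -> IdentifiabilityReport:
    """Collinearity indices of every non-empty subset of ``free``.

    Subsets are keyed by the sorted tuple of parameter names; a subset
    is flagged identifiable when its gamma is at or below ``threshold``.
    """
    S = sensitivities if sensitivities is not None else relative_sensitivities(
        params, geom, input_tac, free=free,
        rel_perturbation=rel_perturbation, output_surface=output_surface,
    )
    gammas = {}
    for r in range(1, len(free) + 1):
        for subset in itertools.combinations(free, r):
            key = tuple(sorted(subset))
            gammas[key] = collinearity_index(S, subset)
    return IdentifiabilityReport(
        gammas=gammas,
        threshold=threshold,
        parameter_names=tuple(free),
        output_surface=S.output_surface,
        normalization=S.normalization,
    )
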