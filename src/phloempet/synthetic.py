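"""Synthetic TAC tables and 4D voxel phantoms.

Stands in for the PET scanner: a gamma-variate input pulse (pulse
labelling produces a bolus-like input whose activity peaks around
65-70 min post labelling) drives the forward model at known "true"
parameters, producing a noiseless ROI set; a noisy copy adds mean-zero
multiplicative Gaussian noise.  The optional 4D phantom paints the
per-frame ROI concentrations into a voxelized stem cylinder so the
image-extraction path can be exercised end to end without any scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import PRIMARY_SHOOT_PARAMS, ModelParameters, SolverConfig, simulate
from .tac import CylindricalRoi, RoiGeometry, TacTable


@dataclass(frozen=True)
class PulseShape:
    """Gamma-variate bolus: A * (t/tp)^alpha * exp(alpha * (1 - t/tp)).

    ``peak_time_min`` is the mode of the continuous pulse;
    ``shape_exponent`` alpha controls the width (larger = narrower).
    """

    peak_time_min: float = 65.0
    shape_exponent: float = 3.0
    amplitude: float = 2.0  # MBq mL^-1 at the peak

    def __post_init__(self) -> None:
        if self.peak_time_min <= 0 or self.amplitude <= 0 or self.shape_exponent <= 0:
            raise ValueError("pulse parameters must be positive")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        x = np.clip(t / self.peak_time_min, 0.0, None)
        a = self.shape_exponent
        with np.errstate(invalid="ignore"):
            v = self.amplitude * x**a * np.exp(a * (1.0 - x))
        return np.where(t <= 0.0, 0.0, v)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise: sd = cv * value + floor, clipped at 0."""

    cv: float = 0.05
    floor: float = 0.001  # MBq mL^-1

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        sd = self.cv * values + self.floor
        return np.clip(values + rng.standard_normal(values.shape) * sd, 0.0, None)


@dataclass(frozen=True)
class SyntheticConfig:
    params: ModelParameters = PRIMARY_SHOOT_PARAMS
    geom: RoiGeometry = field(default_factory=RoiGeometry.primary)
    pulse: PulseShape = field(default_factory=PulseShape)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_frames: int = 24
    frame_width_min: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        span = self.n_frames * self.frame_width_min
        if not 0 < self.pulse.peak_time_min < span:
            raise ValueError(
                f"pulse peak ({self.pulse.peak_time_min} min) must fall inside "
                f"the {span:g}-min frame span"
            )


def generate_input_pulse(cfg: SyntheticConfig, oversample: int = 50) -> np.ndarray:
    """Frame-averaged input-ROI TAC column (one value per frame).

    Frame averages are trapezoidal means of the continuous pulse over
    each frame window, matching how PET frames integrate activity.
    """
    w = cfg.frame_width_min
    out = np.empty(cfg.n_frames)
    for f in range(cfg.n_frames):
        t = np.linspace(f * w, (f + 1) * w, oversample + 1)
        out[f] = np.trapezoid(cfg.pulse(t), t) / w
    return out


def generate_roi_set(
    cfg: SyntheticConfig, solver: SolverConfig | None = None
):
    """Simulate one ROI set at the true parameters.

    Returns ``(noiseless, noisy, truth)``: two :class:`TacTable` objects
    on the standard frame grid and a ground-truth dict (parameters,
    geometry, pulse, noise, seed) suitable for a JSON sidecar.
    """
    t_mid = TacTable.default_grid(cfg.n_frames, cfg.frame_width_min)
    input_col = generate_input_pulse(cfg)
    driver = TacTable(
        t_mid,
        np.column_stack([input_col, np.zeros((cfg.n_frames, 3))]),
        cfg.frame_width_min,
    )
    sim = simulate(cfg.params, cfg.geom, driver, solver=solver, dense=False)
    values = sim.frame_totals.copy()
    values[:, 0] = input_col  # the input column is the measured forcing
    noiseless = TacTable(t_mid, values, cfg.frame_width_min)
    rng = np.random.default_rng(cfg.seed)
    noisy = TacTable(t_mid, cfg.noise.apply(values, rng), cfg.frame_width_min)
    truth = {
        "params": cfg.params.to_dict(),
        "geometry": cfg.geom.to_dict(),
        "pulse": {
            "peak_time_min": cfg.pulse.peak_time_min,
            "shape_exponent": cfg.pulse.shape_exponent,
            "amplitude": cfg.pulse.amplitude,
        },
        "noise": {"cv": cfg.noise.cv, "floor": cfg.noise.floor},
        "seed": cfg.seed,
    }
    return noiseless, noisy, truth


def generate_phantom_4d(
    cfg: SyntheticConfig,
    voxel_size_mm: float = 0.4,
    dims: tuple = (192, 192, 384),
    stem_diameter_mm: float = 1.6,
    blur_fwhm_mm: float = 0.0,
    z_start_mm: float | None = None,
):
    """Paint the ROI-set TACs into a voxelized stem cylinder.

    The stem lies along the z axis through the grid center (the plant is
    scanned horizontally); four consecutive axial segments of length
    ``geom.roi_length_mm`` carry the input/roi1-3 frame concentrations.
    Optionally blurred with an isotropic Gaussian of the scanner's FWHM
    to mimic finite resolution (partial-volume losses for structures
    thinner than ~2 FWHM).

    Returns ``(volume_4d, rois, noiseless_tac)`` where ``volume_4d`` is
    float32 of shape ``(*dims, n_frames)`` and ``rois`` are matching
    :class:`CylindricalRoi` definitions of the painted segments.
    """
    noiseless, _, _ = generate_roi_set(cfg)
    l_mm = cfg.geom.roi_length_mm
    nx, ny, nz = dims
    cx = nx * voxel_size_mm / 2.0
    cy = ny * voxel_size_mm / 2.0
    if z_start_mm is None:
        z_start_mm = (nz * voxel_size_mm - 4 * l_mm) / 2.0
    if z_start_mm < 0 or z_start_mm + 4 * l_mm > nz * voxel_size_mm:
        raise ValueError("stem segments do not fit inside the grid along z")

    x = (np.arange(nx) + 0.5) * voxel_size_mm - cx
    y = (np.arange(ny) + 0.5) * voxel_size_mm - cy
    in_stem = (x[:, None] ** 2 + y[None, :] ** 2) <= (stem_diameter_mm / 2.0) ** 2
    if not in_stem.any():
        raise ValueError("stem diameter too small for the voxel grid")
    zc = (np.arange(nz) + 0.5) * voxel_size_mm

    vol = np.zeros((nx, ny, nz, cfg.n_frames), dtype=np.float32)
    rois = []
    names = ("input", "roi1", "roi2", "roi3")
    for s, name in enumerate(names):
        z0, z1 = z_start_mm + s * l_mm, z_start_mm + (s + 1) * l_mm
        zmask = (zc >= z0) & (zc < z1)
        seg = in_stem[:, :, None] & zmask[None, None, :]
        vol[seg] = noiseless.column(name).astype(np.float32)
        rois.append(
            CylindricalRoi(
                start_mm=(cx, cy, z0),
                end_mm=(cx, cy, z1),
                diameter_mm=stem_diameter_mm,
                label=name,
            )
        )
    if blur_fwhm_mm > 0:
        sigma_vox = blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
        vol = ndimage.gaussian_filter(vol, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0))
    return vol, rois, noiseless
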