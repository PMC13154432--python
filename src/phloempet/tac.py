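"""Time-activity-curve tables and their on-disk formats.

A TAC table holds the decay-corrected mean tracer concentration
(MBq mL^-1) per PET frame for one set of four consecutive cylindrical
stem ROIs: the proximal *input* ROI plus three downstream ROIs.  The CSV
dialect is ``time_min,input,roi1,roi2,roi3`` with one row per frame;
``time_min`` is the frame *midpoint* in minutes post labelling.  A YAML
sidecar carries the ROI geometry and the decay-correction flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ROI_COLUMNS = ("input", "roi1", "roi2", "roi3")


class TacFormatError(ValueError):
    """Raised when a TAC file violates the declared table contract."""


@dataclass(frozen=True)
class RoiGeometry:
    """Geometry of one ROI set along a shoot.

    Parameters
    ----------
    roi_length_mm:
        Axial length ``l`` of each cylindrical ROI (4 mm on primary
        shoots, 10 mm on secondary shoots).
    shoot_class:
        ``"primary"`` or ``"secondary"``.
    n_rois:
        Number of consecutive ROIs (input + 3 downstream).
    position_cm:
        Optional height of the ROI-set midpoint above the rosette.
    stem_diameter_mm:
        Optional local stem diameter (used by the positron module).
    """

    roi_length_mm: float
    shoot_class: str = "primary"
    n_rois: int = 4
    position_cm: float | None = None
    stem_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.roi_length_mm <= 0:
            raise ValueError(f"roi_length_mm must be > 0, got {self.roi_length_mm}")
        if self.n_rois != 4:
            raise ValueError("a ROI set consists of exactly 4 consecutive ROIs")
        if self.shoot_class not in ("primary", "secondary"):
            raise ValueError(f"unknown shoot_class {self.shoot_class!r}")

    @classmethod
    def primary(cls, **kw) -> "RoiGeometry":
        return cls(roi_length_mm=4.0, shoot_class="primary", **kw)

    @classmethod
    def secondary(cls, **kw) -> "RoiGeometry":
        return cls(roi_length_mm=10.0, shoot_class="secondary", **kw)

    def to_dict(self) -> dict:
        return {
            "roi_length_mm": self.roi_length_mm,
            "shoot_class": self.shoot_class,
            "n_rois": self.n_rois,
            "position_cm": self.position_cm,
            "stem_diameter_mm": self.stem_diameter_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoiGeometry":
        return cls(
            roi_length_mm=float(d["roi_length_mm"]),
            shoot_class=d.get("shoot_class", "primary"),
            n_rois=int(d.get("n_rois", 4)),
            position_cm=d.get("position_cm"),
            stem_diameter_mm=d.get("stem_diameter_mm"),
        )


@dataclass(frozen=True)
class TacTable:
    """Per-frame tracer concentrations for one ROI set.

    ``time_min`` are frame midpoints (minutes post labelling), strictly
    increasing; ``values`` is an ``(n_frames, 4)`` array in the column
    order :data:`ROI_COLUMNS`.  The kinetic model contains no
    radioactive-decay term, so only decay-corrected tables are accepted
    for modelling.
    """

    time_min: np.ndarray
    values: np.ndarray
    frame_width_min: float = 5.0
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 2 or v.shape != (t.size, 4):
            raise TacFormatError(
                f"expected time (n,) and values (n, 4); got {t.shape} and {v.shape}"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise TacFormatError(
                f"time_min must be strictly increasing; row {row} "
                f"(t={t[row]:g} min) is out of order"
            )
        if self.frame_width_min <= 0:
            raise TacFormatError("frame_width_min must be positive")

    @property
    def n_frames(self) -> int:
        return self.time_min.size

    @property
    def frame_edges_min(self) -> np.ndarray:
        """Edges [t0 - w/2, ..., tN + w/2] assuming contiguous frames."""
        half = self.frame_width_min / 2.0
        return np.concatenate([self.time_min - half, [self.time_min[-1] + half]])

    def column(self, name: str) -> np.ndarray:
        return self.values[:, ROI_COLUMNS.index(name)]

    @property
    def input(self) -> np.ndarray:
        return self.column("input")

    @property
    def rois(self) -> np.ndarray:
        """The three downstream ROI columns, shape (n_frames, 3)."""
        return self.values[:, 1:]

    def scaled(self, factor: float) -> "TacTable":
        return TacTable(
            self.time_min, self.values * factor, self.frame_width_min, self.decay_corrected
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(ROI_COLUMNS))
        df.insert(0, "time_min", self.time_min)
        return df

    @classmethod
    def default_grid(cls, n_frames: int = 24, frame_width_min: float = 5.0) -> np.ndarray:
        """Frame midpoints of the standard 24 x 5-min acquisition."""
        return (np.arange(n_frames) + 0.5) * frame_width_min


def read_tac_table(path: str | Path, sidecar: str | Path | None = None):
    """Read a TAC CSV (plus optional geometry sidecar).

    Returns ``(TacTable, RoiGeometry | None)``.  Raises
    :class:`TacFormatError` on a missing column or a non-monotone time
    axis, naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("time_min", *ROI_COLUMNS) if c not in df.columns]
    if missing:
        raise TacFormatError(f"{path.name}: missing column(s) {missing}")
    meta: dict = {}
    geom = None
    if sidecar is not None:
        meta = _read_sidecar(sidecar)
        if "geometry" in meta:
            geom = RoiGeometry.from_dict(meta["geometry"])
    t = df["time_min"].to_numpy(dtype=float)
    width = float(meta.get("frame_width_min", np.median(np.diff(t)) if t.size > 1 else 5.0))
    tac = TacTable(
        time_min=t,
        values=df[list(ROI_COLUMNS)].to_numpy(dtype=float),
        frame_width_min=width,
        decay_corrected=bool(meta.get("decay_corrected", True)),
    )
    return tac, geom


def write_tac_table(
    path: str | Path,
    tac: TacTable,
    geom: RoiGeometry | None = None,
    sidecar: str | Path | None = None,
) -> None:
    """Write the TAC CSV; optionally write the YAML sidecar next to it."""
    tac.to_frame().to_csv(path, index=False, float_format="%.17g")
    if sidecar is not None:
        meta = {
            "decay_corrected": tac.decay_corrected,
            "frame_width_min": tac.frame_width_min,
        }
        if geom is not None:
            meta["geometry"] = geom.to_dict()
        with open(sidecar, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def _read_sidecar(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


@dataclass(frozen=True)
class CylindricalRoi:
    """A cylindrical ROI in physical image coordinates (mm).

    Physical coordinates follow the voxel-center convention:
    ``x_mm = (index + 0.5) * voxel_size``.
    """

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    diameter_mm: float
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.start_mm, float)
        b = np.asarray(self.end_mm, float)
        if np.linalg.norm(b - a) <= 0:
            raise ValueError("ROI axis must have positive length")
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")

    def to_dict(self) -> dict:
        return {
            "start_mm": list(map(float, self.start_mm)),
            "end_mm": list(map(float, self.end_mm)),
            "diameter_mm": float(self.diameter_mm),
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CylindricalRoi":
        return cls(
            tuple(d["start_mm"]), tuple(d["end_mm"]), float(d["diameter_mm"]), d.get("label", "")
        )


def voxel_centers_mask(shape, voxel_size_mm: float, roi: CylindricalRoi) -> np.ndarray:
    """Boolean mask of voxels whose centers fall inside the cylinder."""
    a = np.asarray(roi.start_mm, float)
    b = np.asarray(roi.end_mm, float)
    axis = b - a
    length = np.linalg.norm(axis)
    axis = axis / length
    idx = np.indices(shape, dtype=float)
    centers = (idx + 0.5) * voxel_size_mm  # (3, nx, ny, nz)
    rel = centers - a[:, None, None, None]
    proj = np.einsum("i,i...->...", axis, rel)
    radial2 = np.einsum("i...,i...->...", rel, rel) - proj**2
    r = roi.diameter_mm / 2.0
    return (proj >= 0) & (proj <= length) & (radial2 <= r**2 + 1e-12)


def extract_roi_tac(volume_4d: np.ndarray, roi: CylindricalRoi, voxel_size_mm: float) -> np.ndarray:
    """Per-frame mean concentration over the voxels inside ``roi``.

    ``volume_4d`` has shape (nx, ny, nz, n_frames) in MBq mL^-1.  Raises
    ``ValueError`` if no voxel center falls inside the cylinder.
    """
    vol = np.asarray(volume_4d)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {vol.shape}")
    mask = voxel_centers_mask(vol.shape[:3], voxel_size_mm, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"ROI {roi.label or '<unnamed>'} contains no voxel centers "
            f"(diameter {roi.diameter_mm} mm vs voxel {voxel_size_mm} mm)"
        )
    return vol[mask].mean(axis=0)


def write_roi_yaml(path: str | Path, rois: list[CylindricalRoi], voxel_size_mm: float) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "voxel_size_mm": voxel_size_mm,
                "coordinate_convention": "physical = (index + 0.5) * voxel_size_mm",
                "rois": [r.to_dict() for r in rois],
            },
            fh,
            sort_keys=False,
        )


def read_roi_yaml(path: str | Path):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return [CylindricalRoi.from_dict(r) for r in d["rois"]], float(d["voxel_size_mm"])
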