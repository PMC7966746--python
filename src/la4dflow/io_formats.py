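"""On-disk formats and in-memory containers for 4D-flow datasets.

A dataset directory holds three scalar 4D NIfTI volumes (one per velocity
component, cm/s, data axes x,y,z,frame), 0/1 mask volumes on the same grid,
a tracked-contour point table (CSV), and a JSON sidecar with cardiac timing
and acquisition metadata.  Conventions: voxel indices are 0-based, world
coordinates come from the volume affine (mm), time is in ms from the R-wave,
and all time intervals are half-open ``[t0, t1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "VelocityField4D",
    "RoiMask4D",
    "CardiacTimings",
    "ContourSequence",
    "phase_to_velocity",
    "write_velocity_field",
    "read_velocity_field",
    "write_mask",
    "read_mask",
    "write_timings",
    "read_timings",
    "write_contours",
    "read_contours",
    "write_metrics",
]

VALID_REGIONS = ("LA", "LAA", "LV_endo", "LV_epi", "stationary")
CONTOUR_VIEWS = ("2ch", "4ch")


class FormatError(ValueError):
    """Raised when on-disk artifacts are inconsistent or malformed."""


@dataclass
class VelocityField4D:
    """Time-resolved 3-component voxel velocity field.

    ``velocities`` has axes (frame, component x/y/z, i, j, k) in cm/s.
    ``venc_cmps`` is the velocity-encoding sensitivity of the acquisition.
    """

    velocities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    frame_times_ms: np.ndarray
    rr_ms: float
    venc_cmps: float

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if self.velocities.ndim != 5 or self.velocities.shape[1] != 3:
            raise FormatError(
                f"velocities must have shape (frames, 3, i, j, k), got {self.velocities.shape}"
            )
        if not np.all(np.isfinite(self.velocities)):
            raise FormatError("velocity field contains non-finite values")
        if len(self.frame_times_ms) != self.velocities.shape[0]:
            raise FormatError("frame_times_ms length does not match frame count")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise FormatError("frame times must be strictly increasing")
        if self.frame_times_ms[0] < 0 or self.frame_times_ms[-1] >= self.rr_ms:
            raise FormatError("frame times must lie in [0, rr_ms)")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise FormatError("voxel spacing must be positive")
        if self.rr_ms <= 0 or self.venc_cmps <= 0:
            raise FormatError("rr_ms and venc_cmps must be positive")

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocities.shape[2:]

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (mm^3 / 1000)."""
        sx, sy, sz = self.voxel_spacing_mm
        return sx * sy * sz / 1000.0


@dataclass
class RoiMask4D:
    """Per-frame boolean occupancy of a named region on the field grid."""

    occupancy: np.ndarray
    region_name: str
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if self.occupancy.ndim != 4:
            raise FormatError(
                f"mask occupancy must have shape (frames, i, j, k), got {self.occupancy.shape}"
            )
        if self.region_name not in VALID_REGIONS:
            raise FormatError(
                f"unknown region {self.region_name!r}; expected one of {VALID_REGIONS}"
            )
        if self.region_name == "LA" and not self.occupancy.any(axis=(1, 2, 3)).all():
            raise FormatError("LA mask must contain at least one voxel in every frame")

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape[1:]

    def volume_ml(self) -> np.ndarray:
        """Per-frame region volume in mL (voxel count x voxel volume)."""
        sx, sy, sz = self.voxel_spacing_mm
        return self.occupancy.sum(axis=(1, 2, 3)) * (sx * sy * sz / 1000.0)


@dataclass
class CardiacTimings:
    """Cardiac-phase annotations in ms from the R-wave.

    Systole and diastole are half-open intervals; E- and A-wave peaks are
    instants inside diastole; ``t_preac_ms`` marks the volume-curve point
    immediately before atrial contraction.
    """

    systole_ms: tuple[float, float]
    diastole_ms: tuple[float, float]
    t_e_peak_ms: float
    t_a_peak_ms: float
    t_preac_ms: float
    rr_ms: float

    def __post_init__(self) -> None:
        self.systole_ms = (float(self.systole_ms[0]), float(self.systole_ms[1]))
        self.diastole_ms = (float(self.diastole_ms[0]), float(self.diastole_ms[1]))
        s0, s1 = self.systole_ms
        d0, d1 = self.diastole_ms
        if not (0 <= s0 < s1 <= self.rr_ms and 0 <= d0 < d1 <= self.rr_ms):
            raise FormatError("systole/diastole intervals must lie within [0, rr_ms]")
        if max(s0, d0) < min(s1, d1):
            raise FormatError("systole and diastole intervals overlap")
        if not (d0 <= self.t_e_peak_ms < self.t_a_peak_ms < d1):
            raise FormatError("need t_e_peak < t_a_peak, both inside diastole")
        if self.t_preac_ms > self.t_a_peak_ms:
            raise FormatError("t_preac must not be later than the A-wave peak")

    def window(self, name: str) -> tuple[float, float]:
        if name == "systole":
            return self.systole_ms
        if name == "diastole":
            return self.diastole_ms
        if name == "RR":
            return (0.0, self.rr_ms)
        raise KeyError(f"unknown window {name!r}")

    def to_dict(self) -> dict:
        return {
            "systole_ms": list(self.systole_ms),
            "diastole_ms": list(self.diastole_ms),
            "t_e_peak_ms": self.t_e_peak_ms,
            "t_a_peak_ms": self.t_a_peak_ms,
            "t_preac_ms": self.t_preac_ms,
            "rr_ms": self.rr_ms,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CardiacTimings":
        return cls(
            systole_ms=tuple(d["systole_ms"]),
            diastole_ms=tuple(d["diastole_ms"]),
            t_e_peak_ms=float(d["t_e_peak_ms"]),
            t_a_peak_ms=float(d["t_a_peak_ms"]),
            t_preac_ms=float(d["t_preac_ms"]),
            rr_ms=float(d["rr_ms"]),
        )


@dataclass
class ContourSequence:
    """Tracked chamber-boundary contours per cine frame and long-axis view.

    ``points[view]`` has shape (n_frames, n_points, 2) in mm; the polyline is
    open and its two endpoints are the leading-edge mitral-annulus points, so
    the annulus chord is the segment joining them.  Point correspondence is
    maintained across frames (feature tracking), hence the fixed point count.
    """

    times_ms: np.ndarray
    points: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        for view, pts in self.points.items():
            pts = np.asarray(pts, dtype=float)
            self.points[view] = pts
            if pts.ndim != 3 or pts.shape[2] != 2:
                raise FormatError(f"view {view!r}: points must have shape (frames, n, 2)")
            if pts.shape[0] != len(self.times_ms):
                raise FormatError(f"view {view!r}: frame count does not match times")
            if pts.shape[1] < 16:
                raise FormatError(f"view {view!r}: contours need at least 16 points")

    @property
    def views(self) -> tuple[str, ...]:
        return tuple(self.points)

    def annulus_chord(self, view: str, frame: int) -> np.ndarray:
        """The two leading-edge mitral-annulus points of a contour (2, 2)."""
        pts = self.points[view]
        return pts[frame, [0, -1], :]


def phase_to_velocity(phase: np.ndarray, venc_cmps: float) -> np.ndarray:
    """Map phase-contrast phase (rad, in [-pi, pi]) to velocity in cm/s.

    Standard linear PC-MRI convention: full phase range corresponds to +/-VENC,
    i.e. ``v = venc * phase / pi``.
    """
    if venc_cmps <= 0:
        raise ValueError("venc must be positive")
    phase = np.asarray(phase, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise ValueError("phase values outside [-pi, pi]")
    return venc_cmps * phase / np.pi


# ---------------------------------------------------------------------------
# NIfTI velocity volumes and masks
# ---------------------------------------------------------------------------

def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_velocity_field(field_: VelocityField4D, out_dir: str | Path) -> dict[str, Path]:
    """Write one scalar 4D NIfTI per component plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(field_.voxel_spacing_mm)
    paths: dict[str, Path] = {}
    for c, name in enumerate("xyz"):
        # stored with data axes (i, j, k, frame)
        data = np.moveaxis(field_.velocities[:, c], 0, -1)
        p = out_dir / f"vel_{name}.nii"
        nib.save(nib.Nifti1Image(data.astype(np.float64), aff), p)
        paths[name] = p
    meta = {
        "frame_times_ms": field_.frame_times_ms.tolist(),
        "rr_ms": field_.rr_ms,
        "venc_cmps": field_.venc_cmps,
        "voxel_spacing_mm": list(field_.voxel_spacing_mm),
    }
    meta_path = out_dir / "flow_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths["meta"] = meta_path
    return paths


def read_velocity_field(
    paths: Mapping[str, str | Path] | str | Path, meta: Mapping | None = None
) -> VelocityField4D:
    """Assemble a velocity field from three component volumes and metadata.

    ``paths`` may be a dataset directory (written by :func:`write_velocity_field`)
    or a mapping with keys ``x``/``y``/``z`` (and optionally ``meta``).
    """
    if isinstance(paths, (str, Path)):
        d = Path(paths)
        paths = {c: d / f"vel_{c}.nii" for c in "xyz"}
        paths["meta"] = d / "flow_meta.json"
    if meta is None:
        meta_path = paths.get("meta")
        if meta_path is None:
            raise FormatError("no metadata mapping or sidecar path provided")
        meta = json.loads(Path(meta_path).read_text())
    for key in ("frame_times_ms", "rr_ms", "venc_cmps"):
        if key not in meta:
            raise FormatError(f"metadata missing required key {key!r}")
    comps = []
    shapes = []
    spacing = None
    for name in "xyz":
        img = nib.load(str(paths[name]))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise FormatError(f"component {name!r} volume is not 4D")
        shapes.append(data.shape)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        comps.append(np.moveaxis(data, -1, 0))
    if len({s for s in shapes}) != 1:
        raise FormatError(f"component volumes have mismatched shapes: {shapes}")
    velocities = np.stack(comps, axis=1)
    return VelocityField4D(
        velocities=velocities,
        voxel_spacing_mm=tuple(meta.get("voxel_spacing_mm", spacing)),
        frame_times_ms=np.asarray(meta["frame_times_ms"], dtype=float),
        rr_ms=float(meta["rr_ms"]),
        venc_cmps=float(meta["venc_cmps"]),
    )


def write_mask(mask: RoiMask4D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.moveaxis(mask.occupancy.astype(np.uint8), 0, -1)
    nib.save(nib.Nifti1Image(data, _affine(mask.voxel_spacing_mm)), path)
    return path


def read_mask(path: str | Path, region_name: str) -> RoiMask4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError("mask volume is not 4D")
    if not np.isin(np.unique(data), [0, 1]).all():
        raise FormatError("mask volume must be binary 0/1")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return RoiMask4D(np.moveaxis(data, -1, 0) > 0, region_name, spacing)


def write_timings(timings: CardiacTimings, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(timings.to_dict(), indent=1))
    return path


def read_timings(path: str | Path) -> CardiacTimings:
    return CardiacTimings.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Contour tables
# ---------------------------------------------------------------------------

def write_contours(contours: ContourSequence, path: str | Path) -> Path:
    rows = []
    for view in contours.views:
        pts = contours.points[view]
        for f in range(pts.shape[0]):
            for p in range(pts.shape[1]):
                rows.append(
                    {
                        "frame": f,
                        "time_ms": contours.times_ms[f],
                        "view": view,
                        "point_index": p,
                        "x_mm": pts[f, p, 0],
                        "y_mm": pts[f, p, 1],
                    }
                )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8f")
    return path


def read_contours(path: str | Path, require_views: tuple[str, ...] = CONTOUR_VIEWS) -> ContourSequence:
    df = pd.read_csv(path)
    needed = {"frame", "time_ms", "view", "point_index", "x_mm", "y_mm"}
    if not needed.issubset(df.columns):
        raise FormatError(f"contour CSV missing columns {sorted(needed - set(df.columns))}")
    for view in require_views:
        if view not in set(df["view"]):
            raise FormatError(f"contour CSV missing required view {view!r}")
    times = None
    points: dict[str, np.ndarray] = {}
    for view, sub in df.groupby("view"):
        frames = np.sort(sub["frame"].unique())
        if not np.array_equal(frames, np.arange(len(frames))):
            raise FormatError(f"view {view!r}: frames must be 0..n-1 without gaps")
        counts = sub.groupby("frame")["point_index"].count()
        if counts.nunique() != 1:
            raise FormatError(f"view {view!r}: point count varies across frames")
        n_pts = int(counts.iloc[0])
        sub = sub.sort_values(["frame", "point_index"])
        pts = sub[["x_mm", "y_mm"]].to_numpy().reshape(len(frames), n_pts, 2)
        points[view] = pts
        t = sub.groupby("frame")["time_ms"].first().to_numpy()
        if times is None:
            times = t
        elif not np.allclose(times, t):
            raise FormatError("views disagree on frame times")
    return ContourSequence(times_ms=times, points=points)


# ---------------------------------------------------------------------------
# Metric reports
# ---------------------------------------------------------------------------

def write_metrics(records: list[dict], path: str | Path) -> Path:
    """Write a flat metric report (one row per subject/region/metric).

    Each record must carry ``value`` and ``unit`` keys; written as CSV, or
    JSON when the path ends in ``.json``.
    """
    path = Path(path)
    for rec in records:
        if "value" not in rec or "unit" not in rec:
            raise FormatError("each metric record needs 'value' and 'unit'")
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1, default=float))
    else:
        pd.DataFrame(records).to_csv(path, index=False)
    return path
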