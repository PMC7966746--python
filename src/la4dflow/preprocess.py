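"""Residual velocity-offset correction and cine-to-flow temporal alignment.

Phase-contrast velocity maps retain a slowly varying background offset (eddy
currents, concomitant gradients left after scanner-side correction).  Here it
is modelled, per velocity component, as a first-order spatial polynomial
``offset(x, y, z) = a + b*x + c*y + d*z`` (world mm, cm/s), fitted by least
squares to the temporal-mean velocity of automatically detected stationary
tissue, and subtracted from every frame.  The offset is assumed
time-invariant, consistent with its eddy-current origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import RoiMask4D, VelocityField4D

__all__ = [
    "StationaryDetectionError",
    "OffsetPlaneModel",
    "detect_stationary_tissue",
    "fit_offset_plane",
    "correct_offset",
    "resample_masks_to_flow_times",
]


class StationaryDetectionError(RuntimeError):
    pass


@dataclass
class OffsetPlaneModel:
    """Fitted per-component linear offset model.

    ``coefficients`` has shape (3, 4): rows are velocity components x/y/z,
    columns the (a, b, c, d) terms of ``a + b*x + c*y + d*z`` with world
    coordinates in mm and the offset in cm/s.
    """

    coefficients: np.ndarray
    n_stationary_voxels: int
    residual_rmse_cmps: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (3, 4):
            raise ValueError("coefficients must have shape (3, 4)")
        if not np.isfinite(self.residual_rmse_cmps):
            raise ValueError("residual RMSE must be finite")

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "n_stationary_voxels": self.n_stationary_voxels,
            "residual_rmse_cmps": self.residual_rmse_cmps,
        }


def _world_coords(grid_shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.indices(grid_shape, dtype=float)
    return tuple(idx[a] * spacing[a] for a in range(3))


def detect_stationary_tissue(field: VelocityField4D, sd_threshold_cmps: float = 2.0,
                             exclude_masks: list[RoiMask4D] | None = None) -> RoiMask4D:
    """Static mask of voxels whose velocity barely varies over the cycle.

    A voxel qualifies when the temporal standard deviation of each velocity
    component is below ``sd_threshold_cmps`` and it is outside every provided
    chamber mask (any frame).  The result is frame-invariant (replicated
    across frames).
    """
    if sd_threshold_cmps <= 0:
        raise ValueError("sd threshold must be positive")
    temporal_sd = field.velocities.std(axis=0, ddof=1)  # (3, i, j, k)
    static = (temporal_sd < sd_threshold_cmps).all(axis=0)
    if exclude_masks:
        for m in exclude_masks:
            static &= ~m.occupancy.any(axis=0)
    if not static.any():
        raise StationaryDetectionError(
            f"no stationary voxel found at sd threshold {sd_threshold_cmps} cm/s"
        )
    occupancy = np.broadcast_to(static, (field.n_frames, *static.shape)).copy()
    return RoiMask4D(occupancy, "stationary", field.voxel_spacing_mm)


def fit_offset_plane(field: VelocityField4D, stationary_mask: RoiMask4D) -> OffsetPlaneModel:
    """Least-squares fit of the linear offset model on stationary tissue.

    The fit target is the temporal mean velocity of each stationary voxel
    (the offset is time-invariant); the design matrix is [1, x, y, z] in mm.
    """
    static = stationary_mask.occupancy[0]
    if static.shape != field.grid_shape:
        raise ValueError("stationary mask grid does not match field")
    n = int(static.sum())
    if n < 16:
        raise StationaryDetectionError(
            f"only {n} stationary voxels; need at least 16 for a stable plane fit"
        )
    x, y, z = _world_coords(field.grid_shape, field.voxel_spacing_mm)
    design = np.column_stack(
        [np.ones(n), x[static], y[static], z[static]]
    )
    rank = np.linalg.matrix_rank(design)
    if rank < 4:
        raise np.linalg.LinAlgError(
            "stationary voxel positions are degenerate (coplanar/collinear)"
        )
    vmean = field.velocities.mean(axis=0)  # (3, i, j, k)
    targets = np.column_stack([vmean[c][static] for c in range(3)])
    coef, _, _, _ = np.linalg.lstsq(design, targets, rcond=None)
    resid = targets - design @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    return OffsetPlaneModel(coefficients=coef.T, n_stationary_voxels=n,
                            residual_rmse_cmps=rmse)


def correct_offset(field: VelocityField4D, model: OffsetPlaneModel) -> VelocityField4D:
    """Subtract the modelled offset plane from every frame of the field."""
    x, y, z = _world_coords(field.grid_shape, field.voxel_spacing_mm)
    plane = (
        model.coefficients[:, 0, None, None, None]
        + model.coefficients[:, 1, None, None, None] * x
        + model.coefficients[:, 2, None, None, None] * y
        + model.coefficients[:, 3, None, None, None] * z
    )  # (3, i, j, k)
    corrected = field.velocities - plane[None]
    return VelocityField4D(
        velocities=corrected,
        voxel_spacing_mm=field.voxel_spacing_mm,
        frame_times_ms=field.frame_times_ms,
        rr_ms=field.rr_ms,
        venc_cmps=field.venc_cmps,
    )


def resample_masks_to_flow_times(mask_at_cine_times: RoiMask4D, cine_times_ms: np.ndarray,
                                 flow_times_ms: np.ndarray, rr_ms: float) -> RoiMask4D:
    """Nearest-neighbour temporal resampling of cine masks onto flow frames.

    Distance is circular on the R-R interval; an exact tie between two cine
    frames resolves to the earlier (lower-index) frame.
    """
    cine_times = np.asarray(cine_times_ms, dtype=float)
    flow_times = np.asarray(flow_times_ms, dtype=float)
    if cine_times.size == 0 or flow_times.size == 0:
        raise ValueError("cine and flow time grids must be non-empty")
    if mask_at_cine_times.n_frames != cine_times.size:
        raise ValueError("mask frame count does not match cine time grid")
    picked = []
    for t in flow_times:
        d = np.abs(cine_times - t)
        d = np.minimum(d, rr_ms - d)  # wrap-around distance
        picked.append(int(np.argmin(d)))  # argmin takes the earliest on ties
    occupancy = mask_at_cine_times.occupancy[picked]
    return RoiMask4D(occupancy, mask_at_cine_times.region_name,
                     mask_at_cine_times.voxel_spacing_mm)
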