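"""Synthetic dynamic-atrium 4D-flow datasets with known ground truth.

The phantom emulates the measured quantities of an LA 4D-flow exam, not the
physics of the acquisition: the left atrium is a time-varying ellipsoid whose
voxelized volume tracks a prescribed volume curve (max at end of ventricular
systole, pre-ac plateau, minimum after atrial contraction); the appendage is
a small attached spherical lobe excluded from the LA mask.  Voxel speed
follows a temporal envelope (systolic hump, E peak, A peak) multiplied by a
frozen per-voxel lognormal heterogeneity field; directions come from a
smooth, randomly rotated template (metrics depend only on the magnitude).
Gaussian component noise and a linear offset plane are added on top, and the
background tissue is truly stationary.  Flow frames cover only the first
``rr_coverage`` fraction of the R-R interval, as in prospectively gated
acquisitions; cine-derived masks and tracked contours cover the full cycle.

Cohort presets ("control", "af") are calibrated so that, per group, the mean
velocity, stasis fraction, indexed kinetic energy, and heart rate reproduce
the corresponding published group statistics for paroxysmal-AF patients and
controls.  The speed-multiplier mixture (slow-pool fraction and scale) is
solved from two continuum constraints at the group envelope — the pooled
volume-weighted stasis integral and the multiplier second moment implied by
the indexed-KE target — a deterministic root find done once per preset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .chamber_metrics import VolumeCurve
from .flow_metrics import (
    RHO_BLOOD_G_PER_ML,
    STASIS_THRESHOLD_CMPS,
    FlowMetrics,
    RegionError,
)
from .io_formats import (
    CardiacTimings,
    ContourSequence,
    RoiMask4D,
    VelocityField4D,
    read_contours,
    read_mask,
    read_timings,
    read_velocity_field,
    write_contours,
    write_mask,
    write_timings,
    write_velocity_field,
)

__all__ = [
    "GeometryError",
    "CalibrationError",
    "VolumeParams",
    "VelocityParams",
    "AppendageParams",
    "StrainParams",
    "PhantomSpec",
    "GroundTruth",
    "PhantomDataset",
    "CohortSubject",
    "GROUP_TARGETS",
    "NOMINAL_BSA_M2",
    "make_volume_curve",
    "velocity_envelope",
    "make_phantom",
    "make_cohort",
    "oracle_metrics",
    "preset_spec",
    "write_dataset",
    "read_dataset",
]

NOMINAL_BSA_M2 = 1.9
#: ellipsoid semi-axis shape ratios (product ~1 so the cube root sets scale)
_SHAPE_RATIOS = (1.15, 1.0, 0.87)


class GeometryError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


class VolumeParams(BaseModel):
    """LA volume-curve landmarks (mL) and their cycle-phase positions."""

    v_max_ml: float = Field(69.5, gt=0)
    v_preac_ml: float = Field(50.9, gt=0)
    v_min_ml: float = Field(30.0, gt=0)
    t_max_frac: float = Field(0.4, gt=0, lt=1)
    t_preac_frac: float = Field(0.8, gt=0, lt=1)
    t_min_frac: float = Field(0.93, gt=0, lt=1)

    @model_validator(mode="after")
    def _ordering(self) -> "VolumeParams":
        if not (self.v_max_ml >= self.v_preac_ml >= self.v_min_ml):
            raise ValueError("need v_max >= v_preac >= v_min")
        if not (self.t_max_frac < self.t_preac_frac < self.t_min_frac):
            raise ValueError("need t_max_frac < t_preac_frac < t_min_frac")
        return self


class VelocityParams(BaseModel):
    """Temporal speed envelope anchors (cm/s) and spatial heterogeneity.

    The frozen per-voxel speed multiplier is a two-population mixture: a
    ``slow_pool_frac`` share of voxels (recirculating blood pools) scaled by
    ``slow_pool_scale``, the rest a faster transit population, each modulated
    by a lognormal factor with coefficient of variation
    ``spatial_heterogeneity``; the overall multiplier has mean one.  When
    ``mean_rr_cmps`` is set the whole envelope is rescaled so its time
    average over the flow frames equals it; ``envelope_contrast`` then
    compresses the temporal excursion about that mean (1 keeps the raw
    shape).  ``constant_cmps`` overrides the envelope with a flat profile
    (test fixture for exact-value checks).
    """

    systolic_mean_cmps: float = Field(17.4, ge=0)
    e_peak_mean_cmps: float = Field(23.7, ge=0)
    a_peak_mean_cmps: float = Field(12.1, ge=0)
    mean_rr_cmps: Optional[float] = Field(None, gt=0)
    envelope_contrast: float = Field(1.0, gt=0, le=1)
    spatial_heterogeneity: float = Field(0.0, ge=0)
    slow_pool_frac: float = Field(0.0, ge=0, lt=1)
    slow_pool_scale: float = Field(0.35, gt=0, le=1)
    constant_cmps: Optional[float] = Field(None, ge=0)


class AppendageParams(BaseModel):
    """LAA lobe geometry and its reduced velocity scale."""

    velocity_scale: float = Field(0.65, gt=0, le=1)
    radius_mm: float = Field(9.0, gt=0)
    offset_mm: float = Field(4.0, ge=0)


class StrainParams(BaseModel):
    """Prescribed atrial strain phase values (%) for the tracked contours."""

    reservoir_pct: float = Field(20.8, gt=0)
    active_pct: float = Field(6.8, ge=0)

    @model_validator(mode="after")
    def _ordering(self) -> "StrainParams":
        if self.active_pct >= self.reservoir_pct:
            raise ValueError("active strain must be smaller than reservoir strain")
        return self


class PhantomSpec(BaseModel):
    """Full generative parameter set of one synthetic subject."""

    grid_dims: tuple[int, int, int] = (34, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (3.1, 3.1, 3.0)
    n_frames: int = Field(25, ge=8)
    n_cine_frames: int = Field(30, ge=8)
    rr_ms: float = Field(950.0, gt=0)
    rr_coverage: float = Field(0.9, gt=0, le=1)
    volume_params: VolumeParams = Field(default_factory=VolumeParams)
    velocity_params: VelocityParams = Field(default_factory=VelocityParams)
    appendage_params: AppendageParams = Field(default_factory=AppendageParams)
    strain_params: StrainParams = Field(default_factory=StrainParams)
    noise_sd_cmps: float = Field(0.0, ge=0)
    offset_plane: tuple[
        tuple[float, float, float, float],
        tuple[float, float, float, float],
        tuple[float, float, float, float],
    ] = ((0, 0, 0, 0), (0, 0, 0, 0), (0, 0, 0, 0))
    venc_cmps: float = Field(100.0, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _spacing(self) -> "PhantomSpec":
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        return self

    # -- sampling grids -----------------------------------------------------
    def flow_times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * (self.rr_coverage * self.rr_ms) / self.n_frames

    def cine_times_ms(self) -> np.ndarray:
        return np.arange(self.n_cine_frames) * self.rr_ms / self.n_cine_frames

    def timings(self) -> CardiacTimings:
        vp = self.volume_params
        t_es = vp.t_max_frac * self.rr_ms
        return CardiacTimings(
            systole_ms=(0.0, t_es),
            diastole_ms=(t_es, self.rr_ms),
            t_e_peak_ms=(vp.t_max_frac + 0.12) * self.rr_ms,
            t_a_peak_ms=0.5 * (vp.t_preac_frac + vp.t_min_frac) * self.rr_ms,
            t_preac_ms=vp.t_preac_frac * self.rr_ms,
            rr_ms=self.rr_ms,
        )


@dataclass
class GroundTruth:
    """Oracle-computed reference values for recovery testing.

    ``true_metrics`` are brute-force flow metrics of the noiseless,
    offset-free field on the delivered (resampled) masks; landmark volumes
    and strain phases echo the generative parameters.
    """

    true_volume_curve: VolumeCurve
    true_metrics: dict[str, FlowMetrics]
    true_landmark_frames: dict[str, int]
    true_landmarks: dict[str, float]
    true_strain_phases: dict[str, float]
    envelope_cmps: np.ndarray


@dataclass
class PhantomDataset:
    """One synthetic subject: velocity field, masks, contours, timings, truth."""

    field: VelocityField4D
    mask_la: RoiMask4D
    mask_laa: RoiMask4D
    mask_la_cine: RoiMask4D
    mask_laa_cine: RoiMask4D
    cine_times_ms: np.ndarray
    timings: CardiacTimings
    contours: ContourSequence
    truth: Optional[GroundTruth]
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Volume curve and velocity envelope
# ---------------------------------------------------------------------------

def _volume_interpolator(vp: VolumeParams) -> PchipInterpolator:
    knots_x = [vp.t_min_frac - 1.0, vp.t_max_frac, vp.t_preac_frac,
               vp.t_min_frac, 1.0 + vp.t_max_frac]
    knots_y = [vp.v_min_ml, vp.v_max_ml, vp.v_preac_ml, vp.v_min_ml, vp.v_max_ml]
    return PchipInterpolator(knots_x, knots_y)


def volume_at_phase(vp: VolumeParams, phase: np.ndarray) -> np.ndarray:
    """Analytic LA volume (mL) at cycle phase(s) in [0, 1)."""
    return _volume_interpolator(vp)(np.mod(np.asarray(phase, dtype=float), 1.0))


def make_volume_curve(spec: PhantomSpec) -> VolumeCurve:
    """Analytic LA volume curve sampled at the flow frame times.

    The curve is a smooth periodic monotone-piecewise interpolation rising to
    ``v_max`` at the end of ventricular systole, descending to ``v_preac`` at
    the pre-atrial-contraction phase and to ``v_min`` after atrial
    contraction.  Landmarks carry the analytic values and nearest frames.
    """
    times = spec.flow_times_ms()
    phases = times / spec.rr_ms
    vp = spec.volume_params
    vols = volume_at_phase(vp, phases)
    landmarks = {
        "v_max_ml": vp.v_max_ml,
        "v_preac_ml": vp.v_preac_ml,
        "v_min_ml": vp.v_min_ml,
        "frame_max": int(np.argmin(np.abs(phases - vp.t_max_frac))),
        "frame_preac": int(np.argmin(np.abs(phases - vp.t_preac_frac))),
        "frame_min": int(np.argmin(np.abs(phases - vp.t_min_frac))),
    }
    return VolumeCurve(times, vols, landmarks)


def _envelope_interpolator(spec: PhantomSpec) -> PchipInterpolator:
    vp, vel = spec.volume_params, spec.velocity_params
    t_e = vp.t_max_frac + 0.12
    t_a = 0.5 * (vp.t_preac_frac + vp.t_min_frac)
    t_d = 0.5 * (t_e + vp.t_preac_frac)
    sys_m, e_pk, a_pk = (vel.systolic_mean_cmps, vel.e_peak_mean_cmps,
                         vel.a_peak_mean_cmps)
    anchors = [
        (0.0, 0.6 * sys_m),
        (0.55 * vp.t_max_frac, 1.5 * sys_m),
        (vp.t_max_frac, 0.8 * sys_m),
        (t_e, e_pk),
        (t_d, 0.8 * a_pk),
        (t_a, a_pk),
        (vp.t_min_frac, 0.7 * a_pk),
        (1.0, 0.6 * sys_m),
    ]
    xs = [a[0] for a in anchors]
    if np.any(np.diff(xs) <= 0):
        raise ValueError(f"envelope anchor phases not strictly increasing: {xs}")
    # wrap one anchor on each side for a smooth periodic join
    xs = [anchors[-2][0] - 1.0] + xs + [anchors[1][0] + 1.0]
    ys = [anchors[-2][1]] + [a[1] for a in anchors] + [anchors[1][1]]
    return PchipInterpolator(xs, ys)


def velocity_envelope(spec: PhantomSpec, phases: np.ndarray) -> np.ndarray:
    """Spatial-mean speed envelope (cm/s) at cycle phases in [0, 1).

    Rescaled so its average over the flow frames equals ``mean_rr_cmps`` when
    that target is set; constant when ``constant_cmps`` is set.
    """
    phases = np.mod(np.asarray(phases, dtype=float), 1.0)
    vel = spec.velocity_params
    if vel.constant_cmps is not None:
        return np.full(phases.shape, float(vel.constant_cmps))
    interp = _envelope_interpolator(spec)
    vals = interp(phases)
    flow_phases = spec.flow_times_ms() / spec.rr_ms
    raw_mean = float(interp(flow_phases).mean())
    if vel.mean_rr_cmps is not None:
        vals = vals * (vel.mean_rr_cmps / raw_mean)
        raw_mean = vel.mean_rr_cmps
    if vel.envelope_contrast < 1.0:
        vals = raw_mean + vel.envelope_contrast * (vals - raw_mean)
    return np.maximum(vals, 0.0)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _grid_world(spec: PhantomSpec):
    sp = spec.voxel_spacing_mm
    axes = [np.arange(n) * s for n, s in zip(spec.grid_dims, sp)]
    center = [(n - 1) * s / 2.0 for n, s in zip(spec.grid_dims, sp)]
    return axes, center


def _chamber_masks_at(spec: PhantomSpec, phases: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean LA / LAA occupancy (n_phases, i, j, k) at the given phases."""
    vols = volume_at_phase(spec.volume_params, phases)
    p, q, r = _SHAPE_RATIOS
    ap = spec.appendage_params
    axes, center = _grid_world(spec)
    x = axes[0][:, None, None] - center[0]
    y = axes[1][None, :, None] - center[1]
    z = axes[2][None, None, :] - center[2]
    v_max_mm3 = spec.volume_params.v_max_ml * 1000.0
    u_max = (3.0 * v_max_mm3 / (4.0 * math.pi * p * q * r)) ** (1.0 / 3.0)
    half_ext = [(n - 1) * s / 2.0 for n, s in zip(spec.grid_dims, spec.voxel_spacing_mm)]
    margin = max(spec.voxel_spacing_mm)
    if (p * u_max + ap.offset_mm + ap.radius_mm > half_ext[0] - margin
            or q * u_max > half_ext[1] - margin or r * u_max > half_ext[2] - margin):
        raise GeometryError(
            "grid too small: chamber plus appendage does not fit with a "
            "one-voxel stationary margin"
        )
    la = np.empty((len(phases), *spec.grid_dims), dtype=bool)
    laa = np.empty_like(la)
    for f, v_ml in enumerate(vols):
        u = (3.0 * v_ml * 1000.0 / (4.0 * math.pi * p * q * r)) ** (1.0 / 3.0)
        ell = ((x / (p * u)) ** 2 + (y / (q * u)) ** 2 + (z / (r * u)) ** 2) <= 1.0
        scale = (v_ml / spec.volume_params.v_max_ml) ** (1.0 / 3.0)
        cx = p * u + ap.offset_mm
        r_laa = ap.radius_mm * scale
        sph = ((x - cx) ** 2 + y**2 + z**2) <= r_laa**2
        la[f] = ell & ~sph
        laa[f] = sph & ~ell
        if not la[f].any() or not laa[f].any():
            raise GeometryError("empty chamber mask; grid resolution too coarse")
    return la, laa


def _resample_nearest(cine_mask: np.ndarray, cine_times: np.ndarray,
                      flow_times: np.ndarray, rr_ms: float) -> np.ndarray:
    """Wrap-around nearest-neighbour pick of cine frames for each flow frame.

    Deliberately re-implemented here (and used by the ground truth) so the
    preprocessing module's resampler can be tested against it.
    """
    picked = []
    for t in flow_times:
        d = np.abs(cine_times - t)
        d = np.minimum(d, rr_ms - d)
        picked.append(int(np.argmin(d)))
    return cine_mask[picked]


# ---------------------------------------------------------------------------
# Field synthesis
# ---------------------------------------------------------------------------

def _fast_scale(p: float, eta: float) -> float:
    """Fast-population scale keeping the mixture mean at one."""
    return (1.0 - p * eta) / (1.0 - p)


def _heterogeneity_field(spec: PhantomSpec, rng: np.random.Generator,
                         union_mask: np.ndarray) -> np.ndarray:
    vel = spec.velocity_params
    cv, p, eta = (vel.spatial_heterogeneity, vel.slow_pool_frac,
                  vel.slow_pool_scale)
    if cv == 0 and p == 0:
        return np.ones(spec.grid_dims)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    h = np.exp(sigma * rng.standard_normal(spec.grid_dims) - sigma**2 / 2.0)
    if p > 0:
        slow = rng.random(spec.grid_dims) < p
        h *= np.where(slow, eta, _fast_scale(p, eta))
    # anchor the in-chamber sample mean at 1 so the spatial-mean speed tracks
    # the envelope exactly
    h /= h[union_mask].mean()
    return h


def _direction_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth unit direction template with a random rotation, (3, i, j, k)."""
    axes, center = _grid_world(spec)
    ext = [n * s for n, s in zip(spec.grid_dims, spec.voxel_spacing_mm)]
    x = (axes[0][:, None, None] - center[0]) / ext[0]
    y = (axes[1][None, :, None] - center[1]) / ext[1]
    z = (axes[2][None, None, :] - center[2]) / ext[2]
    ph = rng.uniform(0, 2 * math.pi, size=3)
    gx = 1.0 + 0.5 * np.sin(2 * math.pi * y + ph[0])
    gy = 0.6 * np.cos(2 * math.pi * z + ph[1]) + 0.0 * x
    gz = 0.6 * np.sin(2 * math.pi * x + ph[2]) + 0.0 * y
    g = np.stack([np.broadcast_to(gx, spec.grid_dims),
                  np.broadcast_to(gy, spec.grid_dims),
                  np.broadcast_to(gz, spec.grid_dims)])
    rot, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    g = np.einsum("ab,bijk->aijk", rot, g)
    norm_ = np.sqrt((g**2).sum(axis=0))
    return g / norm_


def _offset_plane_values(spec: PhantomSpec) -> np.ndarray:
    coef = np.asarray(spec.offset_plane, dtype=float)
    axes, _ = _grid_world(spec)
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    return (coef[:, 0, None, None, None]
            + coef[:, 1, None, None, None] * x
            + coef[:, 2, None, None, None] * y
            + coef[:, 3, None, None, None] * z)


def _make_contours(spec: PhantomSpec) -> ContourSequence:
    """Tracked open contours whose arc length encodes the prescribed strain."""
    vp, sp = spec.volume_params, spec.strain_params
    times = spec.cine_times_ms()
    phases = times / spec.rr_ms
    eps = PchipInterpolator(
        [vp.t_min_frac - 1.0, 0.0, vp.t_max_frac, vp.t_preac_frac,
         vp.t_min_frac, 1.0],
        [0.0, 0.0, sp.reservoir_pct, sp.active_pct, 0.0, 0.0],
    )(phases)
    lam = 1.0 + eps / 100.0
    points: dict[str, np.ndarray] = {}
    for view, radius, n_pts in (("2ch", 25.0, 33), ("4ch", 28.0, 33)):
        theta = np.linspace(-0.25 * math.pi, 1.25 * math.pi, n_pts)
        base = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        points[view] = lam[:, None, None] * base[None, :, :]
    return ContourSequence(times_ms=times, points=points)


def make_phantom(spec: PhantomSpec, compute_ground_truth: bool = True
                 ) -> PhantomDataset:
    """Generate one synthetic subject dataset.

    The analytic field (envelope x heterogeneity along the direction
    template) is built first; noise and the offset plane are added on top of
    a copy, so with ``noise_sd_cmps = 0`` and a zero offset plane the
    delivered field equals the analytic one exactly.  Ground truth runs the
    brute-force oracle on the analytic field.
    """
    rng = np.random.default_rng(spec.seed)
    flow_times = spec.flow_times_ms()
    cine_times = spec.cine_times_ms()
    flow_phases = flow_times / spec.rr_ms

    la_cine, laa_cine = _chamber_masks_at(spec, cine_times / spec.rr_ms)
    la_flow = _resample_nearest(la_cine, cine_times, flow_times, spec.rr_ms)
    laa_flow = _resample_nearest(laa_cine, cine_times, flow_times, spec.rr_ms)

    h = _heterogeneity_field(spec, rng, la_flow.any(axis=0))
    direction = _direction_field(spec, rng)
    envelope = velocity_envelope(spec, flow_phases)
    scale_laa = spec.appendage_params.velocity_scale

    velocities = np.zeros((spec.n_frames, 3, *spec.grid_dims))
    for f in range(spec.n_frames):
        sp_field = np.zeros(spec.grid_dims)
        sp_field[la_flow[f]] = envelope[f] * h[la_flow[f]]
        sp_field[laa_flow[f]] = scale_laa * envelope[f] * h[laa_flow[f]]
        velocities[f] = direction * sp_field[None]

    def _field(arr: np.ndarray) -> VelocityField4D:
        return VelocityField4D(arr, spec.voxel_spacing_mm, flow_times,
                               spec.rr_ms, spec.venc_cmps)

    analytic = _field(velocities)
    delivered = velocities
    if spec.noise_sd_cmps > 0:
        delivered = delivered + rng.normal(0.0, spec.noise_sd_cmps, velocities.shape)
    if np.any(np.asarray(spec.offset_plane)):
        delivered = delivered + _offset_plane_values(spec)[None]
    if delivered is velocities:
        delivered = velocities.copy()

    mask_la = RoiMask4D(la_flow, "LA", spec.voxel_spacing_mm)
    mask_laa = RoiMask4D(laa_flow, "LAA", spec.voxel_spacing_mm)
    timings = spec.timings()
    contours = _make_contours(spec)

    truth = None
    if compute_ground_truth:
        metrics = oracle_metrics(analytic, {"LA": mask_la, "LAA": mask_laa}, timings)
        curve = make_volume_curve(spec)
        sp = spec.strain_params
        truth = GroundTruth(
            true_volume_curve=curve,
            true_metrics=metrics,
            true_landmark_frames={k: curve.landmarks[k] for k in
                                  ("frame_max", "frame_preac", "frame_min")},
            true_landmarks={k: curve.landmarks[k] for k in
                            ("v_max_ml", "v_preac_ml", "v_min_ml")},
            true_strain_phases={
                "reservoir_strain": sp.reservoir_pct,
                "conduit_strain": sp.reservoir_pct - sp.active_pct,
                "active_strain": sp.active_pct,
            },
            envelope_cmps=envelope,
        )

    return PhantomDataset(
        field=_field(delivered),
        mask_la=mask_la,
        mask_laa=mask_laa,
        mask_la_cine=RoiMask4D(la_cine, "LA", spec.voxel_spacing_mm),
        mask_laa_cine=RoiMask4D(laa_cine, "LAA", spec.voxel_spacing_mm),
        cine_times_ms=cine_times,
        timings=timings,
        contours=contours,
        truth=truth,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def oracle_metrics(field: VelocityField4D, masks: dict[str, RoiMask4D],
                   timings: CardiacTimings) -> dict[str, FlowMetrics]:
    """Flow metrics by direct per-sample enumeration (reference oracle).

    Every statistic is accumulated with explicit Python loops over the
    in-mask voxel indices of every frame; no shared code with the vectorized
    pipeline.  Intended for tests and ground truth, not for throughput.
    """
    if "LA" not in masks:
        raise RegionError("oracle needs an 'LA' mask for KE indexing")
    for m in masks.values():
        if m.occupancy.shape != (field.n_frames, *field.grid_shape):
            raise RegionError("mask grid does not match field grid")
    vox_ml = field.voxel_volume_ml
    times = [float(t) for t in field.frame_times_ms]
    thr = STASIS_THRESHOLD_CMPS

    # max LA volume by counting
    v_max_ml = 0.0
    for f in range(field.n_frames):
        count = 0
        for _ in zip(*np.nonzero(masks["LA"].occupancy[f])):
            count += 1
        v_max_ml = max(v_max_ml, count * vox_ml)

    def window_frames(window: str) -> list[int]:
        if window == "E":
            t0 = timings.t_e_peak_ms
            best = min(range(len(times)), key=lambda f: abs(times[f] - t0))
            return [best]
        if window == "A":
            t0 = timings.t_a_peak_ms
            best = min(range(len(times)), key=lambda f: abs(times[f] - t0))
            return [best]
        lo, hi = timings.window(window)
        return [f for f in range(len(times)) if lo <= times[f] < hi]

    out: dict[str, FlowMetrics] = {}
    for region, mask in masks.items():
        mean_curve: list[float] = []
        ke_curve: list[float] = []
        below_total = 0
        samples_total = 0
        for f in range(field.n_frames):
            total = 0.0
            total_sq = 0.0
            count = 0
            for i, j, k in zip(*np.nonzero(mask.occupancy[f])):
                vx = float(field.velocities[f, 0, i, j, k])
                vy = float(field.velocities[f, 1, i, j, k])
                vz = float(field.velocities[f, 2, i, j, k])
                s = math.sqrt(vx * vx + vy * vy + vz * vz)
                total += s
                total_sq += s * s
                count += 1
                if s < thr:
                    below_total += 1
                samples_total += 1
            if count == 0:
                raise RegionError(f"region {region!r} empty at frame {f}")
            mean_curve.append(total / count)
            ke_curve.append(0.5 * RHO_BLOOD_G_PER_ML * vox_ml * total_sq * 1e-4)

        def stats(curve: list[float], window: str) -> tuple[float, float]:
            frames = window_frames(window)
            vals = [curve[f] for f in frames]
            total = 0.0
            peak = vals[0]
            for v in vals:
                total += v
                if v > peak:
                    peak = v
            return total / len(vals), peak

        v = {w: stats(mean_curve, w) for w in ("RR", "systole", "diastole", "E", "A")}
        k = {w: stats(ke_curve, w) for w in ("RR", "systole", "diastole", "E", "A")}
        out[region] = FlowMetrics(
            region_name=region,
            velocity_mean_rr=v["RR"][0], velocity_peak_rr=v["RR"][1],
            velocity_mean_systole=v["systole"][0], velocity_peak_systole=v["systole"][1],
            velocity_mean_diastole=v["diastole"][0], velocity_peak_diastole=v["diastole"][1],
            velocity_e_wave=v["E"][0], velocity_a_wave=v["A"][0],
            stasis_pct=100.0 * below_total / samples_total,
            ke_mean_rr=k["RR"][0], ke_peak_rr=k["RR"][1],
            ke_mean_systole=k["systole"][0], ke_peak_systole=k["systole"][1],
            ke_mean_diastole=k["diastole"][0], ke_peak_diastole=k["diastole"][1],
            ke_e_wave=k["E"][0], ke_a_wave=k["A"][0],
            kei_mean_rr=k["RR"][0] * 1000.0 / v_max_ml,
            kei_peak_rr=k["RR"][1] * 1000.0 / v_max_ml,
            kei_mean_systole=k["systole"][0] * 1000.0 / v_max_ml,
            kei_peak_systole=k["systole"][1] * 1000.0 / v_max_ml,
            kei_mean_diastole=k["diastole"][0] * 1000.0 / v_max_ml,
            kei_peak_diastole=k["diastole"][1] * 1000.0 / v_max_ml,
            kei_e_wave=k["E"][0] * 1000.0 / v_max_ml,
            kei_a_wave=k["A"][0] * 1000.0 / v_max_ml,
            v_max_ml=v_max_ml,
        )
    return out


# ---------------------------------------------------------------------------
# Cohort presets and calibration
# ---------------------------------------------------------------------------

#: per-group physiological targets the presets are calibrated to reproduce
GROUP_TARGETS = {
    "control": {
        "hr_bpm": (66.0, 7.0),
        "velocity_mean_rr": (16.7, 2.1),
        "stasis_pct": (27.8, 7.9),
        "laa_stasis_pct": (52.8, 16.2),
        "kei_mean_rr": (16.0, 4.5),
        # cross-subject stasis-velocity regression: slope (% per cm/s) and
        # residual sd chosen to reproduce the printed stasis spread and the
        # strong inverse velocity-stasis correlation
        "stasis_slope": -3.6,
        "stasis_resid_sd": 2.4,
        "systolic_mean_cmps": 17.4,
        "e_peak_cmps": 23.7,
        "a_peak_cmps": 12.1,
        "la_vmax_ml_per_m2": (36.6, 6.7),
        "preac_over_max": 26.8 / 36.6,
        "min_over_preac": 15.8 / 26.8,
        "strain_reservoir_pct": (20.8, 3.0),
        "strain_active_pct": (6.8, 1.2),
    },
    "af": {
        "hr_bpm": (59.0, 6.0),
        "velocity_mean_rr": (13.1, 2.4),
        "stasis_pct": (43.2, 10.8),
        "laa_stasis_pct": (73.3, 5.7),
        "kei_mean_rr": (10.6, 3.4),
        "stasis_slope": -4.3,
        "stasis_resid_sd": 3.2,
        "systolic_mean_cmps": 13.3,
        "e_peak_cmps": 17.0,
        "a_peak_cmps": 11.0,
        "la_vmax_ml_per_m2": (39.6, 10.4),
        "preac_over_max": 29.5 / 39.6,
        "min_over_preac": 19.9 / 29.5,
        "strain_reservoir_pct": (15.8, 1.6),
        "strain_active_pct": (6.1, 0.8),
    },
}

GroupName = Literal["control", "af"]


#: within-population lognormal coefficient of variation used by the presets
_PRESET_CV = 0.25


def _calibrate_heterogeneity(envelope: np.ndarray, vol_weights: np.ndarray,
                             stasis_target_pct: float, eh2_target: float,
                             cv: float = _PRESET_CV,
                             threshold: float = STASIS_THRESHOLD_CMPS,
                             ) -> tuple[float, float]:
    """Solve the mixture parameters (slow-pool fraction, slow-pool scale).

    Matches two continuum constraints simultaneously: the pooled (volume-
    weighted) stasis fraction and the second moment E[h^2] of the mean-one
    speed multiplier (which fixes the indexed kinetic energy).  Within each
    population the multiplier is lognormal with the given CV.
    """
    from scipy.optimize import least_squares

    e = np.maximum(np.asarray(envelope, dtype=float), 1e-9)
    w = np.asarray(vol_weights, dtype=float)
    w = w / w.sum()
    sigma = math.sqrt(math.log(1.0 + cv**2))
    s_target = stasis_target_pct / 100.0

    def pop_below(scale: float) -> np.ndarray:
        # P(e * scale * LN(-s^2/2, s) < thr) per frame
        z = (np.log(threshold / (e * scale))) / sigma + sigma / 2.0
        return norm.cdf(z)

    def residuals(x: np.ndarray) -> np.ndarray:
        p, eta = x
        zeta = _fast_scale(p, eta)
        stasis = float((w * (p * pop_below(eta) + (1 - p) * pop_below(zeta))).sum())
        eh2 = (p * eta**2 + (1 - p) * zeta**2) * math.exp(sigma**2)
        return np.array([stasis - s_target, eh2 - eh2_target])

    sol = least_squares(residuals, x0=np.array([0.25, 0.4]),
                        bounds=([1e-3, 0.05], [0.9, 0.95]), xtol=1e-14)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise CalibrationError(
            f"stasis {stasis_target_pct}% with E[h^2] {eh2_target:.3f} is "
            f"unreachable (residual {sol.fun})"
        )
    return float(sol.x[0]), float(sol.x[1])


#: temporal contrast of the preset envelopes (see methods note)
_PRESET_CONTRAST = 0.6


def _build_spec(group: GroupName, *, mean_rr_cmps: float, hr_bpm: float,
                v_max_ml: float, preac_ratio: float, min_ratio: float,
                reservoir_pct: float, active_pct: float, noise_sd_cmps: float,
                offset_plane, seed: int,
                mixture: tuple[float, float] | None = None,
                **overrides) -> PhantomSpec:
    t = GROUP_TARGETS[group]
    vel_scale = mean_rr_cmps / t["velocity_mean_rr"][0]
    p_g, eta_g, laa_scale = _group_mixture(group)
    p, eta = mixture if mixture is not None else (p_g, eta_g)
    return PhantomSpec(
        rr_ms=60000.0 / hr_bpm,
        volume_params=VolumeParams(
            v_max_ml=v_max_ml,
            v_preac_ml=v_max_ml * preac_ratio,
            v_min_ml=v_max_ml * preac_ratio * min_ratio,
        ),
        velocity_params=VelocityParams(
            systolic_mean_cmps=t["systolic_mean_cmps"] * vel_scale,
            e_peak_mean_cmps=t["e_peak_cmps"] * vel_scale,
            a_peak_mean_cmps=t["a_peak_cmps"] * vel_scale,
            mean_rr_cmps=mean_rr_cmps,
            envelope_contrast=_PRESET_CONTRAST,
            spatial_heterogeneity=_PRESET_CV,
            slow_pool_frac=p,
            slow_pool_scale=eta,
        ),
        appendage_params=AppendageParams(velocity_scale=laa_scale),
        strain_params=StrainParams(reservoir_pct=reservoir_pct, active_pct=active_pct),
        noise_sd_cmps=noise_sd_cmps,
        offset_plane=offset_plane,
        seed=seed,
        **overrides,
    )


def _mixture_stasis(envelope: np.ndarray, weights: np.ndarray, p: float,
                    eta: float, scale: float = 1.0,
                    cv: float = _PRESET_CV,
                    threshold: float = STASIS_THRESHOLD_CMPS) -> float:
    """Continuum pooled stasis fraction of the mixture model (0-1)."""
    sigma = math.sqrt(math.log(1.0 + cv**2))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    e = np.maximum(np.asarray(envelope, dtype=float) * scale, 1e-9)

    def pop_below(s: float) -> np.ndarray:
        return norm.cdf(np.log(threshold / (e * s)) / sigma + sigma / 2.0)

    zeta = _fast_scale(p, eta)
    return float((w * (p * pop_below(eta) + (1 - p) * pop_below(zeta))).sum())


@lru_cache(maxsize=None)
def _group_mixture(group: GroupName) -> tuple[float, float, float]:
    """Slow-pool mixture and LAA velocity scale solved once per group.

    The mixture (p, eta) matches the group LA stasis and indexed-KE means at
    the group envelope; the appendage velocity scale then matches the group
    LAA stasis mean with the same mixture.
    """
    t = GROUP_TARGETS[group]
    v_max_ml = t["la_vmax_ml_per_m2"][0] * NOMINAL_BSA_M2
    base = PhantomSpec(
        rr_ms=60000.0 / t["hr_bpm"][0],
        volume_params=VolumeParams(
            v_max_ml=v_max_ml,
            v_preac_ml=v_max_ml * t["preac_over_max"],
            v_min_ml=v_max_ml * t["preac_over_max"] * t["min_over_preac"],
        ),
        velocity_params=VelocityParams(
            systolic_mean_cmps=t["systolic_mean_cmps"],
            e_peak_mean_cmps=t["e_peak_cmps"],
            a_peak_mean_cmps=t["a_peak_cmps"],
            mean_rr_cmps=t["velocity_mean_rr"][0],
            envelope_contrast=_PRESET_CONTRAST,
        ),
    )
    flow_phases = base.flow_times_ms() / base.rr_ms
    envelope = velocity_envelope(base, flow_phases)
    volumes = volume_at_phase(base.volume_params, flow_phases)
    # E[h^2] implied by the indexed-KE target:
    # KEI = 0.5*rho*1e-4 * mean_t(V(t) e(t)^2) * E[h^2] * 1000 / V_max
    a_factor = (0.5 * RHO_BLOOD_G_PER_ML * 1e-4 * 1000.0
                * float(np.mean(volumes * envelope**2)) / v_max_ml)
    eh2_target = t["kei_mean_rr"][0] / a_factor
    p, eta = _calibrate_heterogeneity(envelope, volumes, t["stasis_pct"][0],
                                      eh2_target)
    from scipy.optimize import brentq

    laa_target = t["laa_stasis_pct"][0] / 100.0

    def f(scale: float) -> float:
        return _mixture_stasis(envelope, volumes, p, eta, scale) - laa_target

    if f(0.05) * f(1.0) > 0:
        raise CalibrationError(f"LAA stasis target {laa_target} unreachable")
    laa_scale = float(brentq(f, 0.05, 1.0, xtol=1e-10))
    return p, eta, laa_scale


def preset_spec(group: GroupName, seed: int = 0, noise_sd_cmps: float = 0.0,
                offset_plane=((0, 0, 0, 0),) * 3, **overrides) -> PhantomSpec:
    """Group-mean phantom spec ('control' or 'af'), stasis-calibrated.

    Volumes de-index the published mL/m^2 group means with a nominal body
    surface area of 1.9 m^2.
    """
    if group not in GROUP_TARGETS:
        raise ValueError(f"unknown group {group!r}")
    t = GROUP_TARGETS[group]
    return _build_spec(
        group,
        mean_rr_cmps=t["velocity_mean_rr"][0],
        hr_bpm=t["hr_bpm"][0],
        v_max_ml=t["la_vmax_ml_per_m2"][0] * NOMINAL_BSA_M2,
        preac_ratio=t["preac_over_max"],
        min_ratio=t["min_over_preac"],
        reservoir_pct=t["strain_reservoir_pct"][0],
        active_pct=t["strain_active_pct"][0],
        noise_sd_cmps=noise_sd_cmps,
        offset_plane=offset_plane,
        seed=seed,
        **overrides,
    )


@dataclass
class CohortSubject:
    """A labelled cohort member; ``build()`` materializes the dataset."""

    subject_id: str
    group: GroupName
    spec: PhantomSpec

    def build(self, compute_ground_truth: bool = True) -> PhantomDataset:
        return make_phantom(self.spec, compute_ground_truth=compute_ground_truth)


def _subject_mixture(spec: PhantomSpec, stasis_pct: float,
                     kei_target: float) -> tuple[float, float] | None:
    """Solve a subject's slow-pool mixture for its own stasis/KE targets.

    Returns None when the pair is numerically unreachable for this
    subject's envelope (the caller falls back to the group mixture).
    """
    flow_phases = spec.flow_times_ms() / spec.rr_ms
    envelope = velocity_envelope(spec, flow_phases)
    volumes = volume_at_phase(spec.volume_params, flow_phases)
    a_factor = (0.5 * RHO_BLOOD_G_PER_ML * 1e-4 * 1000.0
                * float(np.mean(volumes * envelope**2))
                / spec.volume_params.v_max_ml)
    try:
        return _calibrate_heterogeneity(envelope, volumes, stasis_pct,
                                        kei_target / a_factor)
    except CalibrationError:
        return None


def make_cohort(n_af: int, n_ctrl: int, seed: int = 0,
                noise_sd_cmps: float = 1.0, **overrides) -> list[CohortSubject]:
    """Sample a labelled two-group cohort of phantom subjects.

    Subject parameters are drawn around the group presets with the published
    between-subject spreads, in antithetic pairs so that cohort means stay
    centred on the group targets at moderate n.  Each subject's stasis
    target follows its drawn mean velocity through the group-level inverse
    regression (steep negative slope plus a residual), reproducing the
    strong velocity-stasis anticorrelation; the indexed-KE target scales
    with the squared velocity.  Per-subject mixtures are then re-solved, and
    each subject gets a reproducible field seed derived from the master seed
    by a fixed increment.
    """
    if n_af < 1 or n_ctrl < 1:
        raise ValueError("each group needs at least one subject")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    index = 0
    for group, n in (("control", n_ctrl), ("af", n_af)):
        t = GROUP_TARGETS[group]
        m_g, m_sd = t["velocity_mean_rr"]
        cv_m2 = (m_sd / m_g) ** 2
        z = u = None
        for i in range(n):
            index += 1
            subject_seed = (seed + 1000003 * index) % (2**31)
            if i % 2 == 0:
                z = rng.standard_normal(9)
                u = rng.uniform(size=12)
            else:
                z, u = -z, 1.0 - u
            hr = float(np.clip(t["hr_bpm"][0] + t["hr_bpm"][1] * z[0], 45, 100))
            m = float(np.clip(m_g + m_sd * z[1], 6.0, 40.0))
            v_max = float(np.clip(
                t["la_vmax_ml_per_m2"][0] + t["la_vmax_ml_per_m2"][1] * z[2],
                18.0, 60.0)) * NOMINAL_BSA_M2
            preac_ratio = float(np.clip(t["preac_over_max"] + 0.05 * z[3],
                                        0.55, 0.95))
            min_ratio = float(np.clip(t["min_over_preac"] + 0.06 * z[4],
                                      0.35, 0.92))
            reservoir = float(np.clip(
                t["strain_reservoir_pct"][0] + t["strain_reservoir_pct"][1] * z[5],
                8.0, 40.0))
            active = float(np.clip(
                t["strain_active_pct"][0] + t["strain_active_pct"][1] * z[6],
                1.0, 0.8 * reservoir))
            # per-subject targets: KE tracks the squared velocity (the
            # 1 + cv^2 divisor keeps the cohort mean on the group target);
            # stasis follows the inverse velocity regression
            kei_s = (t["kei_mean_rr"][0] * (m / m_g) ** 2 / (1.0 + cv_m2)
                     * math.exp(0.08 * z[7]))
            stasis_s = float(np.clip(
                t["stasis_pct"][0] + t["stasis_slope"] * (m - m_g)
                + t["stasis_resid_sd"] * z[8], 3.0, 92.0))
            offset = tuple(
                (float(-1.5 + 3.0 * u[4 * c]),
                 float(-0.02 + 0.04 * u[4 * c + 1]),
                 float(-0.02 + 0.04 * u[4 * c + 2]),
                 float(-0.02 + 0.04 * u[4 * c + 3]))
                for c in range(3)
            )
            spec = _build_spec(
                group,
                mean_rr_cmps=m,
                hr_bpm=hr,
                v_max_ml=v_max,
                preac_ratio=preac_ratio,
                min_ratio=min_ratio,
                reservoir_pct=reservoir,
                active_pct=active,
                noise_sd_cmps=noise_sd_cmps,
                offset_plane=offset,
                seed=subject_seed,
                **overrides,
            )
            mixture = _subject_mixture(spec, stasis_s, kei_s)
            if mixture is not None:
                vel = spec.velocity_params.model_copy(
                    update={"slow_pool_frac": mixture[0],
                            "slow_pool_scale": mixture[1]})
                spec = spec.model_copy(update={"velocity_params": vel})
            subjects.append(CohortSubject(f"{group}_{i:03d}", group, spec))
    return subjects


# ---------------------------------------------------------------------------
# Dataset persistence
# ---------------------------------------------------------------------------

def write_dataset(ds: PhantomDataset, out_dir: str | Path) -> Path:
    """Write a phantom dataset in the standard on-disk layout."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_velocity_field(ds.field, out_dir)
    write_mask(ds.mask_la_cine, out_dir / "mask_la_cine.nii")
    write_mask(ds.mask_laa_cine, out_dir / "mask_laa_cine.nii")
    write_timings(ds.timings, out_dir / "timings.json")
    write_contours(ds.contours, out_dir / "contours.csv")
    meta = {
        "cine_times_ms": ds.cine_times_ms.tolist(),
        "spec": ds.spec.model_dump(),
    }
    if ds.truth is not None:
        meta["ground_truth"] = {
            "true_landmarks": ds.truth.true_landmarks,
            "true_landmark_frames": ds.truth.true_landmark_frames,
            "true_strain_phases": ds.truth.true_strain_phases,
            "true_metrics": {r: m.as_dict() for r, m in ds.truth.true_metrics.items()},
            "envelope_cmps": ds.truth.envelope_cmps.tolist(),
            "true_volumes_ml": ds.truth.true_volume_curve.volumes_ml.tolist(),
        }
    (out_dir / "phantom_meta.json").write_text(json.dumps(meta, indent=1))
    return out_dir


def read_dataset(in_dir: str | Path) -> PhantomDataset:
    """Read a dataset written by :func:`write_dataset` (ground truth included
    only as raw JSON in ``spec``-level metadata; oracle metrics can be
    recomputed from the spec)."""
    in_dir = Path(in_dir)
    field = read_velocity_field(in_dir)
    meta = json.loads((in_dir / "phantom_meta.json").read_text())
    spec = PhantomSpec(**meta["spec"])
    cine_times = np.asarray(meta["cine_times_ms"], dtype=float)
    mask_la_cine = read_mask(in_dir / "mask_la_cine.nii", "LA")
    mask_laa_cine = read_mask(in_dir / "mask_laa_cine.nii", "LAA")
    la_flow = _resample_nearest(mask_la_cine.occupancy, cine_times,
                                field.frame_times_ms, spec.rr_ms)
    laa_flow = _resample_nearest(mask_laa_cine.occupancy, cine_times,
                                 field.frame_times_ms, spec.rr_ms)
    return PhantomDataset(
        field=field,
        mask_la=RoiMask4D(la_flow, "LA", spec.voxel_spacing_mm),
        mask_laa=RoiMask4D(laa_flow, "LAA", spec.voxel_spacing_mm),
        mask_la_cine=mask_la_cine,
        mask_laa_cine=mask_laa_cine,
        cine_times_ms=cine_times,
        timings=read_timings(in_dir / "timings.json"),
        contours=read_contours(in_dir / "contours.csv"),
        truth=None,
        spec=spec,
    )
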