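"""LA volume/function decomposition, LV biplane volumetry, and strain phases.

The LA volume curve yields three landmarks — maximum volume (end of
ventricular systole), volume before atrial contraction (pre-ac), and minimum
volume — from which the classical decomposition follows:

    reservoir = max - min            total   = 100 * reservoir / max
    conduit   = max - pre-ac         passive = 100 * conduit / max
    active    = pre-ac - min         booster = 100 * active / pre-ac

Longitudinal strain comes from tracked boundary contours: the percent change
of contour arc length relative to the ventricular end-diastolic reference
frame, averaged pointwise in time over the 2- and 4-chamber views.  The
atrial strain curve splits into the same three phases (reservoir peak,
conduit, active emptying); its time derivative yields the peak positive,
peak early negative, and peak late negative strain rates.  Conduit/active
strain and the negative rate peaks are conventionally reported as positive
magnitudes with an implied negative sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CardiacTimings, ContourSequence, RoiMask4D

__all__ = [
    "LandmarkError",
    "TimingError",
    "VolumeCurve",
    "ChamberFunction",
    "StrainCurves",
    "StrainPhases",
    "volume_from_mask",
    "volume_from_slice_areas",
    "find_landmarks",
    "chamber_function",
    "lv_biplane_area_length",
    "lv_mass",
    "ejection_fraction",
    "gls_curve",
    "strain_phases",
]

MYOCARDIUM_DENSITY_G_PER_ML = 1.05


class LandmarkError(ValueError):
    pass


class TimingError(ValueError):
    pass


@dataclass
class VolumeCurve:
    """Chamber volume over the cardiac cycle with optional landmarks."""

    times_ms: np.ndarray
    volumes_ml: np.ndarray
    landmarks: dict | None = None

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.volumes_ml = np.asarray(self.volumes_ml, dtype=float)
        if len(self.times_ms) != len(self.volumes_ml):
            raise ValueError("times and volumes must have equal length")
        if np.any(self.volumes_ml < 0):
            raise ValueError("volumes cannot be negative")


@dataclass
class ChamberFunction:
    """Phasic LA volumes (mL) and fractional function (%)."""

    reservoir_ml: float
    conduit_ml: float
    active_ml: float
    total_pct: float
    passive_pct: float
    booster_pct: float


@dataclass
class StrainCurves:
    """Global longitudinal strain and strain-rate profiles.

    ``gls_pct`` is zero at the reference frame; ``strain_rate_per_s`` is the
    centered finite difference of strain (as a fraction) over time.
    """

    times_ms: np.ndarray
    gls_pct: np.ndarray
    strain_rate_per_s: np.ndarray
    reference_frame: int

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.gls_pct = np.asarray(self.gls_pct, dtype=float)
        self.strain_rate_per_s = np.asarray(self.strain_rate_per_s, dtype=float)


@dataclass
class StrainPhases:
    """Phase strains (%) and strain-rate peaks (1/s), magnitudes for the
    conventionally negative quantities."""

    reservoir_strain: float
    conduit_strain: float
    active_strain: float
    peak_positive_rate: float
    peak_early_negative_rate: float
    peak_late_negative_rate: float


def volume_from_mask(mask: RoiMask4D, times_ms: np.ndarray) -> VolumeCurve:
    """Volume curve by voxel counting: volume(t) = count * voxel volume."""
    counts = mask.occupancy.sum(axis=(1, 2, 3))
    if np.any(counts == 0):
        raise LandmarkError(f"region {mask.region_name!r} empty at some frames")
    return VolumeCurve(times_ms, mask.volume_ml())


def volume_from_slice_areas(slice_areas_mm2: np.ndarray, slice_increment_mm: float) -> float:
    """Slice-summation volumetry: sum of slice areas x slice increment -> mL.

    For a contiguous stack acquired with a gap, the increment is slice
    thickness + gap.
    """
    areas = np.asarray(slice_areas_mm2, dtype=float)
    if np.any(areas < 0) or slice_increment_mm <= 0:
        raise ValueError("areas must be nonnegative and increment positive")
    return float(areas.sum() * slice_increment_mm / 1000.0)


def find_landmarks(curve: VolumeCurve, timings: CardiacTimings) -> dict:
    """Locate max, pre-ac, and min volume landmarks on a volume curve.

    v_max/v_min are the curve extrema; v_preac is the curve value at the
    frame nearest the annotated pre-atrial-contraction time.
    """
    v = curve.volumes_ml
    i_max = int(np.argmax(v))
    i_min = int(np.argmin(v))
    i_preac = int(np.argmin(np.abs(curve.times_ms - timings.t_preac_ms)))
    v_max, v_min, v_preac = float(v[i_max]), float(v[i_min]), float(v[i_preac])
    if not (v_min <= v_preac <= v_max):
        raise LandmarkError(
            f"pre-ac volume {v_preac:.2f} outside [{v_min:.2f}, {v_max:.2f}]; "
            "check the pre-ac annotation"
        )
    return {
        "v_max_ml": v_max,
        "v_preac_ml": v_preac,
        "v_min_ml": v_min,
        "frame_max": i_max,
        "frame_preac": i_preac,
        "frame_min": i_min,
    }


def chamber_function(landmarks: dict) -> ChamberFunction:
    """Reservoir/conduit/active volumes and total/passive/booster function."""
    v_max = float(landmarks["v_max_ml"])
    v_preac = float(landmarks["v_preac_ml"])
    v_min = float(landmarks["v_min_ml"])
    if not (v_max >= v_preac >= v_min):
        raise LandmarkError("landmark ordering v_max >= v_preac >= v_min violated")
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    reservoir = v_max - v_min
    conduit = v_max - v_preac
    active = v_preac - v_min
    if v_preac == 0 and active > 0:
        raise ZeroDivisionError("booster function undefined for v_preac = 0")
    return ChamberFunction(
        reservoir_ml=reservoir,
        conduit_ml=conduit,
        active_ml=active,
        total_pct=reservoir * 100.0 / v_max,
        passive_pct=conduit * 100.0 / v_max,
        booster_pct=(active * 100.0 / v_preac) if v_preac > 0 else 0.0,
    )


def lv_biplane_area_length(area_2ch_mm2: float, area_4ch_mm2: float,
                           length_mm: float) -> float:
    """Biplane area-length LV volume: V = 8*A2c*A4c / (3*pi*L), in mL."""
    if min(area_2ch_mm2, area_4ch_mm2, length_mm) <= 0:
        raise ValueError("areas and length must be positive")
    return 8.0 * area_2ch_mm2 * area_4ch_mm2 / (3.0 * np.pi * length_mm) / 1000.0


def lv_mass(v_epi_ml: float, v_endo_ml: float,
            density_g_per_ml: float = MYOCARDIUM_DENSITY_G_PER_ML) -> float:
    """LV mass from epi-/endocardial volumes, myocardium density 1.05 g/mL."""
    if v_epi_ml < v_endo_ml:
        raise ValueError("epicardial volume must not be smaller than endocardial")
    return density_g_per_ml * (v_epi_ml - v_endo_ml)


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """EF (%) = (EDV - ESV) * 100 / EDV."""
    if not edv_ml >= esv_ml >= 0 or edv_ml <= 0:
        raise ValueError("need edv >= esv >= 0 and edv > 0")
    return (edv_ml - esv_ml) * 100.0 / edv_ml


def _arc_length(points: np.ndarray) -> np.ndarray:
    """Per-frame open-polyline arc length for points of shape (frames, n, 2)."""
    seg = np.diff(points, axis=1)
    return np.sqrt((seg**2).sum(axis=2)).sum(axis=1)


def gls_curve(contours: ContourSequence, reference_frame: int = 0,
              smooth_rate: bool = False) -> StrainCurves:
    """Global longitudinal strain from tracked contours.

    Per view, strain(t) = 100 * (L(t) - L(ref)) / L(ref) with L the contour
    arc length; the global curve averages the views pointwise in time.  The
    strain rate is the centered finite difference of strain/100 (1/s), with an
    optional 3-frame moving average applied to the strain before
    differentiation.
    """
    strains = []
    for view in contours.views:
        pts = contours.points[view]
        L = _arc_length(pts)
        strains.append(100.0 * (L - L[reference_frame]) / L[reference_frame])
    gls = np.mean(strains, axis=0)
    s = gls.copy()
    if smooth_rate:
        kernel = np.ones(3) / 3.0
        s = np.convolve(np.pad(s, 1, mode="edge"), kernel, mode="valid")
    t_s = contours.times_ms / 1000.0
    rate = np.gradient(s / 100.0, t_s)
    return StrainCurves(contours.times_ms, gls, rate, reference_frame)


def strain_phases(curve: StrainCurves, timings: CardiacTimings) -> StrainPhases:
    """Split an atrial strain curve into reservoir/conduit/active phases.

    reservoir = peak strain; active = strain at the pre-ac time (magnitude);
    conduit = reservoir - active.  Rate peaks: maximum rate overall, minimum
    rate between the strain peak and pre-ac (early negative), and minimum rate
    from pre-ac to the end of the curve (late negative), both reported as
    magnitudes.
    """
    i_peak = int(np.argmax(curve.gls_pct))
    reservoir = float(curve.gls_pct[i_peak])
    i_preac = int(np.argmin(np.abs(curve.times_ms - timings.t_preac_ms)))
    if i_preac <= i_peak:
        raise TimingError("pre-ac time does not follow the strain peak")
    active = float(curve.gls_pct[i_preac])
    conduit = reservoir - active
    early = curve.strain_rate_per_s[i_peak + 1 : i_preac]
    late = curve.strain_rate_per_s[i_preac:]
    if early.size == 0 or late.size == 0:
        raise TimingError("empty strain-rate sub-window between peak and pre-ac/end")
    peak_early_neg = float(early.min())
    peak_late_neg = float(late.min())
    if peak_early_neg >= 0 or peak_late_neg >= 0:
        raise TimingError("no negative strain rate in an emptying phase "
                          "(monotone or degenerate strain curve)")
    return StrainPhases(
        reservoir_strain=reservoir,
        conduit_strain=conduit,
        active_strain=active,
        peak_positive_rate=float(curve.strain_rate_per_s.max()),
        peak_early_negative_rate=-peak_early_neg,
        peak_late_negative_rate=-peak_late_neg,
    )
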