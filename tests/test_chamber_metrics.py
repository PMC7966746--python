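import numpy as np
import pytest
from hypothesis import given, strategies as st

from la4dflow import phantom as ph
from la4dflow.chamber_metrics import (
    LandmarkError,
    TimingError,
    VolumeCurve,
    chamber_function,
    ejection_fraction,
    find_landmarks,
    gls_curve,
    lv_biplane_area_length,
    lv_mass,
    strain_phases,
    volume_from_mask,
    volume_from_slice_areas,
)
from la4dflow.io_formats import CardiacTimings, ContourSequence, RoiMask4D


def timings_preac(t_preac, rr=900.0):
    t_a = max(0.87 * rr, t_preac)
    return CardiacTimings(systole_ms=(0, 0.4 * rr), diastole_ms=(0.4 * rr, rr),
                          t_e_peak_ms=0.52 * rr, t_a_peak_ms=t_a,
                          t_preac_ms=t_preac, rr_ms=rr)


class TestVolumeFromMask:
    def test_thousand_unit_voxels_is_one_ml(self):
        occ = np.zeros((1, 10, 10, 10), dtype=bool)
        occ[0] = True
        curve = volume_from_mask(RoiMask4D(occ, "LA", (1, 1, 1)), np.array([0.0]))
        assert curve.volumes_ml[0] == pytest.approx(1.0)

    def test_volume_invariant_when_counts_compensate_spacing(self):
        occ_fine = np.ones((1, 8, 8, 8), dtype=bool)
        occ_coarse = np.ones((1, 4, 4, 4), dtype=bool)
        v_fine = volume_from_mask(RoiMask4D(occ_fine, "LA", (1, 1, 1)),
                                  np.array([0.0]))
        v_coarse = volume_from_mask(RoiMask4D(occ_coarse, "LA", (2, 2, 2)),
                                    np.array([0.0]))
        assert v_fine.volumes_ml[0] == v_coarse.volumes_ml[0]

    def test_phantom_ellipsoid_tracks_analytic_volume(self, control_dataset):
        spec = control_dataset.spec
        curve = volume_from_mask(control_dataset.mask_la_cine,
                                 control_dataset.cine_times_ms)
        analytic = ph.volume_at_phase(spec.volume_params,
                                      control_dataset.cine_times_ms / spec.rr_ms)
        measured = curve.volumes_ml + control_dataset.mask_laa_cine.volume_ml()
        assert np.abs(measured / analytic - 1).max() < 0.06

    def test_slice_summation_with_gap(self):
        # 3 slices of 1000 mm^2, thickness+gap = 10 mm -> 30 mL
        assert volume_from_slice_areas([1000, 1000, 1000], 10.0) == pytest.approx(30.0)


class TestLandmarks:
    def test_constant_curve_landmarks_all_equal(self):
        curve = VolumeCurve(np.linspace(0, 800, 9), np.full(9, 50.0))
        lm = find_landmarks(curve, timings_preac(700.0))
        assert lm["v_max_ml"] == lm["v_preac_ml"] == lm["v_min_ml"] == 50.0

    def test_preac_at_curve_maximum_gives_zero_conduit(self):
        times = np.linspace(0, 800, 9)
        vols = np.array([30, 40, 55, 70, 65, 60, 55, 45, 35.0])
        curve = VolumeCurve(times, vols)
        lm = find_landmarks(curve, timings_preac(300.0))  # nearest frame = max
        cf = chamber_function(lm)
        assert cf.conduit_ml == 0.0

    def test_phantom_landmarks_recovered(self, af_dataset):
        curve = volume_from_mask(af_dataset.mask_la_cine, af_dataset.cine_times_ms)
        lm = find_landmarks(curve, af_dataset.timings)
        for key, truth in af_dataset.truth.true_landmarks.items():
            assert lm[key] == pytest.approx(truth, rel=0.02), key


class TestChamberFunction:
    def test_control_group_reservoir_and_conduit_arithmetic(self):
        cf = chamber_function({"v_max_ml": 36.6, "v_preac_ml": 26.8,
                               "v_min_ml": 15.8})
        assert cf.reservoir_ml == pytest.approx(20.8)
        assert cf.conduit_ml == pytest.approx(9.8)

    def test_af_group_active_emptying_arithmetic(self):
        cf = chamber_function({"v_max_ml": 39.6, "v_preac_ml": 29.5,
                               "v_min_ml": 19.9})
        assert cf.active_ml == pytest.approx(9.6)

    def test_motionless_chamber_zero_function(self):
        cf = chamber_function({"v_max_ml": 50.0, "v_preac_ml": 50.0,
                               "v_min_ml": 50.0})
        assert cf.reservoir_ml == cf.total_pct == 0.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(LandmarkError):
            chamber_function({"v_max_ml": 30.0, "v_preac_ml": 40.0,
                              "v_min_ml": 20.0})

    @given(st.floats(20, 150), st.floats(0.3, 1.0), st.floats(0.3, 1.0))
    def test_identities_on_random_landmarks(self, v_max, r1, r2):
        v_preac = v_max * r1
        v_min = v_preac * r2
        cf = chamber_function({"v_max_ml": v_max, "v_preac_ml": v_preac,
                               "v_min_ml": v_min})
        assert cf.reservoir_ml == pytest.approx(cf.conduit_ml + cf.active_ml)
        assert cf.total_pct == pytest.approx(100.0 * cf.reservoir_ml / v_max)
        assert cf.passive_pct == pytest.approx(100.0 * cf.conduit_ml / v_max)
        assert cf.booster_pct == pytest.approx(100.0 * cf.active_ml / v_preac)


class TestLeftVentricle:
    def test_biplane_sphere_limit(self):
        # equal circular areas and L = 2r reduce to the sphere volume
        r = 30.0
        area = np.pi * r**2
        vol = lv_biplane_area_length(area, area, 2 * r)
        assert vol == pytest.approx(4 / 3 * np.pi * r**3 / 1000.0, rel=1e-12)
        assert vol == pytest.approx(113.1, abs=0.05)

    def test_ejection_fraction_formula(self):
        assert ejection_fraction(173.4, 61.8) == pytest.approx(64.36, abs=0.01)

    def test_equal_epi_endo_volumes_zero_mass(self):
        assert lv_mass(120.0, 120.0) == 0.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lv_biplane_area_length(-1.0, 100.0, 50.0)
        with pytest.raises(ValueError):
            ejection_fraction(50.0, 60.0)


def sinusoidal_contours(n_frames=60, amp=0.1, rr=1000.0):
    """Contours whose arc length oscillates as L0*(1 + amp*sin(2 pi t/rr))."""
    times = np.arange(n_frames) * rr / n_frames
    lam = 1.0 + amp * np.sin(2 * np.pi * times / rr)
    theta = np.linspace(0, np.pi, 40)
    base = 30.0 * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    pts = lam[:, None, None] * base[None]
    return ContourSequence(times_ms=times, points={"2ch": pts, "4ch": pts.copy()}), lam


class TestStrain:
    def test_constant_contours_zero_strain_and_rate(self):
        contours, _ = sinusoidal_contours(amp=0.0)
        curves = gls_curve(contours)
        np.testing.assert_allclose(curves.gls_pct, 0.0)
        np.testing.assert_allclose(curves.strain_rate_per_s, 0.0)

    def test_twenty_percent_lengthening_is_twenty_percent_strain(self):
        times = np.array([0.0, 100.0])
        pts = np.zeros((2, 16, 2))
        pts[0, :, 0] = np.linspace(0, 100, 16)
        pts[1, :, 0] = np.linspace(0, 120, 16)
        contours = ContourSequence(times_ms=times, points={"2ch": pts})
        curves = gls_curve(contours)
        assert curves.gls_pct[1] == pytest.approx(20.0)

    def test_strain_rate_matches_analytic_derivative(self):
        contours, lam = sinusoidal_contours(n_frames=100, amp=0.1)
        curves = gls_curve(contours)
        t_s = contours.times_ms / 1000.0
        analytic = 0.1 * 2 * np.pi * np.cos(2 * np.pi * t_s) / 1.0
        # centered differences: keep interior frames
        np.testing.assert_allclose(curves.strain_rate_per_s[2:-2],
                                   analytic[2:-2], atol=0.02)

    def test_point_count_mismatch_rejected(self):
        times = np.array([0.0, 100.0])
        pts = np.zeros((2, 16, 2))
        with pytest.raises(Exception, match="16|points"):
            ContourSequence(times_ms=times, points={"2ch": pts[:, :10]})


class TestStrainPhases:
    def test_triangular_curve_phase_arithmetic(self):
        rr = 1000.0
        times = np.arange(0, 1000, 50.0)
        strain = np.interp(times, [0, 400, 800, 950], [0, 20, 6.8, 0])
        rate = np.gradient(strain / 100.0, times / 1000.0)
        from la4dflow.chamber_metrics import StrainCurves

        curves = StrainCurves(times, strain, rate, 0)
        phases = strain_phases(curves, timings_preac(800.0, rr))
        assert phases.reservoir_strain == pytest.approx(20.0)
        assert phases.active_strain == pytest.approx(6.8)
        assert phases.conduit_strain == pytest.approx(13.2)

    def test_monotone_strain_rejected(self):
        times = np.arange(0, 1000, 50.0)
        strain = np.linspace(0, 20, len(times))
        rate = np.gradient(strain / 100.0, times / 1000.0)
        from la4dflow.chamber_metrics import StrainCurves

        curves = StrainCurves(times, strain, rate, 0)
        with pytest.raises(TimingError):
            strain_phases(curves, timings_preac(800.0))

    def test_phantom_strain_phases_recovered(self, control_dataset):
        curves = gls_curve(control_dataset.contours)
        phases = strain_phases(curves, control_dataset.timings)
        truth = control_dataset.truth.true_strain_phases
        assert phases.reservoir_strain == pytest.approx(
            truth["reservoir_strain"], rel=0.01)
        assert phases.active_strain == pytest.approx(
            truth["active_strain"], rel=0.01)
        assert phases.conduit_strain == pytest.approx(
            truth["conduit_strain"], rel=0.01)
        assert phases.peak_positive_rate > 0
        assert phases.peak_early_negative_rate > 0
        assert phases.peak_late_negative_rate > 0
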