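import numpy as np
import pytest
from hypothesis import given, strategies as st

from la4dflow import phantom as ph
from la4dflow.flow_metrics import (
    RegionError,
    TimingWindowError,
    compare_la_vs_laa,
    compute_flow_metrics,
    index_ke,
    kinetic_energy_curve,
    speed,
    stasis_fraction,
    velocity_time_curve,
    window_ke_stats,
    window_velocity_stats,
)
from la4dflow.io_formats import CardiacTimings, RoiMask4D, VelocityField4D

from conftest import make_random_field


def tiny_field(vel, spacing=(3.0, 3.0, 3.2), rr=900.0):
    vel = np.asarray(vel, dtype=float)
    times = np.arange(vel.shape[0]) * 0.9 * rr / vel.shape[0]
    return VelocityField4D(vel, spacing, times, rr, 100.0)


def full_mask(field, region="LA"):
    return RoiMask4D(np.ones((field.n_frames, *field.grid_shape), dtype=bool),
                     region, field.voxel_spacing_mm)


def default_timings(rr=900.0):
    return CardiacTimings(systole_ms=(0, 0.4 * rr), diastole_ms=(0.4 * rr, rr),
                          t_e_peak_ms=0.52 * rr, t_a_peak_ms=0.86 * rr,
                          t_preac_ms=0.8 * rr, rr_ms=rr)


class TestSpeed:
    def test_pythagorean_triple(self):
        vel = np.zeros((1, 3, 1, 1, 1))
        vel[0, :, 0, 0, 0] = [3.0, 4.0, 0.0]
        assert speed(tiny_field(vel))[0, 0, 0, 0] == 5.0

    def test_zero_field(self):
        assert np.all(speed(tiny_field(np.zeros((2, 3, 2, 2, 2)))) == 0)

    def test_matches_elementwise_oracle_on_random_field(self):
        rng = np.random.default_rng(0)
        vel = rng.normal(size=(3, 3, 2, 2, 2))
        s = speed(tiny_field(vel))
        for f in range(3):
            for i in range(2):
                for j in range(2):
                    for k in range(2):
                        expect = np.sqrt(sum(vel[f, c, i, j, k] ** 2 for c in range(3)))
                        assert s[f, i, j, k] == pytest.approx(expect, rel=1e-14)


class TestVelocityTimeCurve:
    def test_homogeneous_field_constant_curve(self):
        vel = np.zeros((4, 3, 2, 2, 2))
        vel[:, 0] = 12.0
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        np.testing.assert_allclose(curve.spatial_mean_cmps, 12.0)

    def test_two_voxel_average(self):
        vel = np.zeros((1, 3, 2, 1, 1))
        vel[0, 0, 0, 0, 0] = 10.0
        vel[0, 0, 1, 0, 0] = 20.0
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        assert curve.spatial_mean_cmps[0] == 15.0

    def test_empty_mask_frame_rejected(self):
        field = tiny_field(np.zeros((2, 3, 2, 2, 2)))
        occ = np.ones((2, 2, 2, 2), dtype=bool)
        occ[1] = False
        with pytest.raises(RegionError):
            velocity_time_curve(field, RoiMask4D(occ, "LAA", field.voxel_spacing_mm))


class TestWindowStats:
    def test_constant_curve_same_in_every_window(self):
        vel = np.zeros((10, 3, 2, 2, 2))
        vel[:, 1] = 12.0
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        for window in ("RR", "systole", "diastole", "E", "A"):
            assert window_velocity_stats(curve, default_timings(), window) == (12.0, 12.0)

    def test_mean_and_peak_over_full_rr(self):
        vel = np.zeros((3, 3, 1, 1, 1))
        vel[:, 0, 0, 0, 0] = [10.0, 20.0, 30.0]
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        assert window_velocity_stats(curve, default_timings(), "RR") == (20.0, 30.0)

    def test_e_wave_uses_nearest_frame_value(self):
        vel = np.zeros((10, 3, 1, 1, 1))
        vel[:, 0, 0, 0, 0] = np.arange(10.0) + 1
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        t = default_timings()
        nearest = int(np.argmin(np.abs(field.frame_times_ms - t.t_e_peak_ms)))
        mean, peak = window_velocity_stats(curve, t, "E")
        assert mean == peak == curve.spatial_mean_cmps[nearest]

    def test_window_without_frames_raises(self):
        vel = np.zeros((3, 3, 1, 1, 1))
        field = tiny_field(vel)
        curve = velocity_time_curve(field, full_mask(field))
        rr = 900.0
        narrow = CardiacTimings(systole_ms=(351.0, 352.0),
                                diastole_ms=(352.0, rr),
                                t_e_peak_ms=500.0, t_a_peak_ms=800.0,
                                t_preac_ms=700.0, rr_ms=rr)
        with pytest.raises(TimingWindowError):
            window_velocity_stats(curve, narrow, "systole")


class TestStasis:
    def test_zero_field_full_stasis_both_modes(self):
        field = tiny_field(np.zeros((4, 3, 3, 3, 3)))
        for mode in ("timefrac", "strict"):
            assert stasis_fraction(field, full_mask(field), mode=mode) == 100.0

    def test_fast_field_zero_stasis(self):
        vel = np.zeros((4, 3, 3, 3, 3))
        vel[:, 2] = 20.0
        field = tiny_field(vel)
        assert stasis_fraction(field, full_mask(field)) == 0.0

    def test_half_of_samples_below_threshold(self):
        vel = np.zeros((2, 3, 2, 1, 1))
        vel[0, 0] = 5.0   # frame 0: both voxels below
        vel[1, 0] = 20.0  # frame 1: both voxels above
        field = tiny_field(vel)
        assert stasis_fraction(field, full_mask(field)) == 50.0

    def test_strict_mode_counts_always_slow_voxels(self):
        vel = np.zeros((2, 3, 2, 1, 1))
        vel[:, 0, 0] = 5.0          # voxel 0 always slow
        vel[0, 0, 1] = 5.0          # voxel 1 slow then fast
        vel[1, 0, 1] = 20.0
        field = tiny_field(vel)
        assert stasis_fraction(field, full_mask(field), mode="strict") == 50.0
        assert stasis_fraction(field, full_mask(field)) == 75.0

    def test_strict_mode_uses_mask_intersection(self):
        vel = np.zeros((2, 3, 2, 1, 1))
        vel[:, 0, 0] = 5.0
        vel[:, 0, 1] = 5.0
        field = tiny_field(vel)
        occ = np.ones((2, 2, 1, 1), dtype=bool)
        occ[1, 1] = False  # voxel 1 leaves the mask at frame 1
        mask = RoiMask4D(occ, "LA", field.voxel_spacing_mm)
        assert stasis_fraction(field, mask, mode="strict") == 100.0


class TestKineticEnergy:
    def test_zero_field_zero_ke(self):
        field = tiny_field(np.zeros((3, 3, 2, 2, 2)))
        np.testing.assert_array_equal(kinetic_energy_curve(field, full_mask(field)), 0.0)

    def test_single_voxel_hand_value(self):
        vel = np.zeros((1, 3, 1, 1, 1))
        vel[0, 0] = 20.0
        field = tiny_field(vel)  # voxel 3.0*3.0*3.2 mm^3 = 0.0288 mL
        ke = kinetic_energy_curve(field, full_mask(field))
        assert ke[0] == pytest.approx(5.904e-4, rel=1e-12)

    def test_window_stats_on_ke_curve(self):
        ke = np.array([1.0, 2.0, 3.0])
        times = np.array([0.0, 300.0, 600.0])
        assert window_ke_stats(ke, times, default_timings(), "RR") == (2.0, 3.0)

    def test_index_ke_conversion(self):
        assert index_ke(1.0, 50.0) == 20.0
        assert index_ke(0.0, 50.0) == 0.0
        # unit check at study-scale magnitudes
        assert index_ke(0.95, 59.4) == pytest.approx(15.993, abs=1e-3)

    def test_index_ke_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            index_ke(1.0, 0.0)


class TestScalingProperties:
    @given(st.floats(min_value=1.0, max_value=10.0),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_ke_scales_quadratically_and_stasis_never_increases(self, s, seed):
        rng = np.random.default_rng(seed)
        field, masks, timings = make_random_field(rng, dims=(4, 4, 4), n_frames=4)
        scaled = VelocityField4D(field.velocities * s, field.voxel_spacing_mm,
                                 field.frame_times_ms, field.rr_ms, field.venc_cmps)
        mask = masks["LA"]
        ke0 = kinetic_energy_curve(field, mask)
        ke1 = kinetic_energy_curve(scaled, mask)
        np.testing.assert_allclose(ke1, ke0 * s**2, rtol=1e-12)
        assert (stasis_fraction(scaled, mask)
                <= stasis_fraction(field, mask))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_pipeline_matches_bruteforce_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        field, masks, timings = make_random_field(rng)
        oracle = ph.oracle_metrics(field, masks, timings)
        pipeline = compute_flow_metrics(field, masks, timings)
        for region in masks:
            for key, val in oracle[region].as_dict().items():
                if isinstance(val, float):
                    assert pipeline[region].as_dict()[key] == pytest.approx(
                        val, rel=1e-10, abs=1e-12), (region, key)


class TestLaVsLaa:
    def test_identical_regions_zero_deltas(self):
        rng = np.random.default_rng(1)
        field, masks, timings = make_random_field(rng)
        masks["LAA"] = RoiMask4D(masks["LA"].occupancy.copy(), "LAA",
                                 field.voxel_spacing_mm)
        metrics = compute_flow_metrics(field, masks, timings)
        deltas = compare_la_vs_laa(metrics)
        assert all(v == 0.0 for v in deltas.values())

    def test_slow_appendage_has_negative_velocity_positive_stasis_delta(
            self, control_dataset):
        metrics = compute_flow_metrics(
            control_dataset.field,
            {"LA": control_dataset.mask_la, "LAA": control_dataset.mask_laa},
            control_dataset.timings)
        deltas = compare_la_vs_laa(metrics)
        assert deltas["d_velocity_mean_rr"] < 0
        assert deltas["d_velocity_peak_rr"] < 0
        assert deltas["d_stasis_pct"] > 0

    def test_missing_region_rejected(self):
        rng = np.random.default_rng(2)
        field, masks, timings = make_random_field(rng)
        metrics = compute_flow_metrics(field, {"LA": masks["LA"]}, timings)
        with pytest.raises(RegionError):
            compare_la_vs_laa(metrics)


def test_cohort_velocity_stasis_anticorrelation(cohort_la_metrics):
    """Across a simulated cohort, mean velocity and stasis are strongly
    inversely related, echoing the study's velocity-stasis coupling."""
    from la4dflow.stats_report import spearman

    v = [r["velocity_mean_rr"] for r in cohort_la_metrics]
    s = [r["stasis_pct"] for r in cohort_la_metrics]
    rho, p = spearman(v, s)
    assert rho < -0.8
    assert p < 1e-6
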