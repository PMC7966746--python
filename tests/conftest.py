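import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from la4dflow.io_formats import CardiacTimings, RoiMask4D, VelocityField4D

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_random_field(rng: np.random.Generator, dims=(6, 6, 6), n_frames=8,
                      spacing=(3.1, 3.1, 3.0), vel_scale=25.0, rr_ms=900.0):
    """A random velocity field with random (non-empty) LA/LAA masks and
    plausible cardiac timings, for oracle-equivalence testing."""
    times = np.arange(n_frames) * 0.9 * rr_ms / n_frames
    vel = rng.normal(0.0, vel_scale / 2.0, size=(n_frames, 3, *dims))
    field = VelocityField4D(vel, spacing, times, rr_ms, 100.0)
    masks = {}
    for region in ("LA", "LAA"):
        occ = rng.random((n_frames, *dims)) < 0.5
        for f in range(n_frames):
            if not occ[f].any():
                occ[f, tuple(rng.integers(0, d) for d in dims)] = True
        masks[region] = RoiMask4D(occ, region, spacing)
    t_es = 0.4 * rr_ms
    timings = CardiacTimings(
        systole_ms=(0.0, t_es), diastole_ms=(t_es, rr_ms),
        t_e_peak_ms=0.52 * rr_ms, t_a_peak_ms=0.86 * rr_ms,
        t_preac_ms=0.8 * rr_ms, rr_ms=rr_ms,
    )
    return field, masks, timings


@pytest.fixture(scope="session")
def control_dataset():
    from la4dflow import phantom as ph

    return ph.make_phantom(ph.preset_spec("control", seed=3))


@pytest.fixture(scope="session")
def af_dataset():
    from la4dflow import phantom as ph

    return ph.make_phantom(ph.preset_spec("af", seed=5))


@pytest.fixture(scope="session")
def cohort_la_metrics():
    """Oracle LA metrics of a 30+30 phantom cohort (shared; ~10 s)."""
    from la4dflow import phantom as ph

    rows = []
    for subject in ph.make_cohort(n_af=30, n_ctrl=30, seed=11):
        ds = subject.build()
        tm = ds.truth.true_metrics["LA"]
        rows.append(
            {
                "group": subject.group,
                "velocity_mean_rr": tm.velocity_mean_rr,
                "stasis_pct": tm.stasis_pct,
                "kei_mean_rr": tm.kei_mean_rr,
            }
        )
    return rows
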