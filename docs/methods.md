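# Methods

This note documents the models, conventions, and numerical choices behind
`la4dflow`, and what the synthetic phantom does and does not establish.

## Flow metrics: definitions and conventions

All hemodynamic read-outs derive from the voxel speed
`|v| = √(vx² + vy² + vz²)` (cm/s) of a velocity field sampled on a regular
grid over the cardiac cycle, restricted to a region-of-interest mask
(LA, LAA).

- **Velocity–time curve.** The arithmetic mean of in-mask voxel speeds per
  frame. *Mean* over a window is the time average of this curve across the
  frames whose times fall in the half-open window; *peak* is the curve
  maximum over the same frames. "Peak velocity" is therefore the temporal
  maximum of the spatially averaged curve, not a single-voxel extreme —
  the convention implied by deriving both statistics from velocity–time
  curves. E- and A-wave values are the curve value at the single frame
  nearest the annotated peak time (no averaging window).
- **Stasis.** Default `timefrac` mode: 100 × (in-mask voxel-frame samples
  with speed < 10 cm/s) / (all in-mask voxel-frame samples). The phrase
  "below threshold during the entire cardiac cycle" also admits a stricter
  per-voxel reading, provided as `strict` mode: the share of voxels (on the
  all-frame mask intersection) below threshold at *every* frame. Both are
  implemented; neither is asserted to be the original software's choice.
  The two differ substantially (strict ≤ timefrac), so reports must name
  the mode.
- **Kinetic energy.** `KE(t) = Σ ½ ρ V_voxel |v|²` with ρ = 1.025 g/mL and
  V_voxel in mL; the raw unit g·cm²/s² converts to mJ by 1e-4. Windowed
  KE statistics reuse the velocity-curve convention for symmetry. Indexed
  KE divides by the maximum LA volume (µJ/mL = mJ × 1000 / mL); the
  pipeline uses the mask-derived (voxel-count) maximum volume so that
  absolute and indexed entries stay mutually consistent.
- **Whole-cycle statistics** use the frames actually acquired. Prospective
  gating truncates coverage to ~90 % of the R-R interval, and "R-R" window
  statistics are computed on the available frames without extrapolation.

## Offset correction

Residual phase-contrast velocity offsets are modelled per component as a
global first-order spatial polynomial in world coordinates (mm), fitted by
ordinary least squares to the *temporal mean* velocity of stationary
voxels. Choices and rationale:

- *Global first-order fit* rather than per-slice fits: the standard reading
  of a "spatial linear interpolation" of stationary-tissue offsets, and
  statistically more stable at this voxel count.
- *Time-invariant offset* (fit on the temporal mean): consistent with the
  eddy-current origin of the offset and with a single correction step.
- *Stationary tissue detection*: voxels whose per-component temporal
  standard deviation is below a threshold (default 2 cm/s, configurable)
  and which lie outside any provided chamber mask. The fit refuses fewer
  than 16 stationary voxels or a spatially degenerate (rank < 4) design.
- Correction is subtraction of the fitted plane from every frame; on
  noiseless data with an injected plane it cancels exactly, and refitting
  the corrected field returns coefficients at numerical zero.

Cine-derived masks are aligned to flow frames by nearest-neighbour in time
with wrap-around at the R-R interval and ties resolved toward the
earlier frame — no contour morphing is invented beyond what temporal
co-registration requires.

## Chamber function and strain

Volume curves come from voxel counting (count × voxel volume); a
slice-summation variant (Σ area × increment, increment = thickness + gap)
covers stacks acquired with gaps. Landmarks: v_max and v_min are curve
extrema; v_preac is the curve value at the frame nearest the annotated
pre-atrial-contraction time — the pre-ac instant is an *input*
(ECG/inflow-derived annotation), not an algorithmic detection. The
decomposition follows the standard identities (reservoir = conduit +
active holds exactly by construction).

Strain operates on tracked contours (point correspondence across frames is
the tracking software's job and is input here). Per view, strain is the
percent arc-length change of the open boundary polyline relative to
ventricular end-diastole (frame 0) — the prevailing feature-tracking
reference convention; the global curve averages the 2- and 4-chamber views
pointwise in time (not phase-value averaging). Strain rate is the centered
finite difference of strain/100 over time, with an optional 3-frame moving
average (off by default). Phases: reservoir = peak strain; active = strain
at the pre-ac frame; conduit = reservoir − active. Conventionally negative
quantities (conduit/active strain, negative rate peaks) are reported as
positive magnitudes.

## Statistics

- Normality gate: Shapiro–Wilk at α = 0.05 per group routes `auto`
  comparisons to Welch's t-test (both normal) or Mann–Whitney U.
  Welch is the default t variant given unequal group sizes; the pooled
  test remains available.
- Fisher's exact test is two-sided by probability summation (summing all
  hypergeometric tables no more probable than the observed one), which
  reproduces published two-decimal p-values for the study-sized tables.
- ICC: two-way random effects, absolute agreement, single measures —
  ICC(2,1) — with the F-based 95 % CI, the standard inter-observer
  convention (the model is reported alongside the estimate).
- No multiple-testing correction, matching exploratory-study practice.

## The phantom: what it emulates

`make_phantom` produces a dataset whose *measured quantities* behave like
an LA 4D-flow exam; it makes no attempt at acquisition physics (no k-space,
no phase wrapping, no Navier–Stokes realism — all declared non-goals).

- **Geometry.** The LA is an ellipsoid (axis ratios 1.15 : 1.0 : 0.87)
  whose volume tracks a smooth periodic curve through the three landmarks
  (monotone piecewise-cubic interpolation: rises to v_max at end
  ventricular systole, falls to v_preac at the pre-ac phase and to v_min
  after atrial contraction). The LAA is a small sphere attached beyond the
  long axis, excluded from the LA mask; both masks are voxelized at
  flow-like resolution (3.1 × 3.1 × 3.0 mm default) on cine and flow time
  grids. Default timing fractions put end-systole at 0.40, pre-ac at 0.80
  (aligned with a cine frame so annotation and sampling agree), and the
  volume minimum at 0.93 of the cycle.
- **Velocity.** Per-voxel speed = temporal envelope × frozen per-voxel
  multiplier. The envelope interpolates anchors expressing a systolic
  hump, an E peak, a diastasis trough, and an A peak; it is rescaled so
  its time average over the acquired frames equals the subject's mean
  R-R velocity. Directions come from a smooth, randomly rotated unit
  template — every reported metric depends only on speed, so the direction
  model is documented rather than validated. Gaussian component noise and
  a linear offset plane are added last; background tissue is truly
  stationary. With zero noise and offset, the delivered field equals the
  analytic field bit-for-bit, and a fixed seed reproduces the dataset
  exactly.
- **Spatial heterogeneity.** The multiplier is a mean-one, two-population
  mixture: a *slow-pool* fraction (scale < 1, emulating recirculating
  near-wall blood pools) and a faster transit population, each modulated
  by a mean-one lognormal with CV 0.25. The mixture is what lets the
  phantom satisfy a mean velocity, a stasis fraction, *and* an indexed-KE
  level simultaneously — a single lognormal has no second-moment freedom
  left once mean and stasis are fixed.

### Preset calibration

Group presets (`control`, `af`) must reproduce published group means of
LA mean velocity, stasis, indexed KE mean, LAA stasis, and heart rate.
Calibration is deterministic and closed-form-driven:

1. The envelope's temporal contrast is compressed to 0.6 about the mean.
   With the raw envelope, the temporal second moment alone exceeds what the
   published indexed-KE level permits once stasis is matched; compressing
   the excursion restores joint feasibility. The cost is deliberate: the
   preset's window-specific velocities (systolic mean, E/A peaks) sit
   closer to the cycle mean than the published per-window values, which
   are *not* calibration targets.
2. The slow-pool fraction and scale solve two continuum equations at the
   group envelope: the pooled volume-weighted stasis integral
   `Σ_t w_t [p Φ(z_t(η)) + (1−p) Φ(z_t(ζ))] = stasis target` (w_t ∝ LA
   volume, matching the pooled voxel-frame counting of the stasis metric)
   and the multiplier second moment implied by the indexed-KE target.
3. The LAA velocity scale then solves the same stasis integral for the
   published LAA stasis mean.

Cohort sampling (`make_cohort`) draws subject parameters around the
presets with the published between-subject spreads, in antithetic pairs so
cohort means stay centred at moderate n. Each subject's stasis target
follows its drawn velocity through a steep inverse regression (slope and
residual chosen to reproduce the published stasis spread and the strong
velocity–stasis anticorrelation), its indexed-KE target scales with
velocity squared (with a 1 + cv² divisor so aggregation stays unbiased),
and its own mixture is re-solved; infeasible subjects fall back to the
group mixture. Per-subject field seeds derive from the master seed by a
fixed increment, all below 2³¹.

The printed group standard deviations conflate biological and measurement
variability; the split chosen here (between-subject parameter draws plus
1 cm/s component noise) is one defensible allocation, documented, not
recovered from the study.

### Ground truth and the oracle

`oracle_metrics` recomputes every flow metric by explicit per-sample
enumeration (plain Python loops over in-mask voxel indices), sharing no
code with the vectorized pipeline; it is the equivalence reference in
tests (agreement to 1e-10 relative) and supplies each dataset's
`GroundTruth` on the noiseless, offset-free field. Landmark and strain
ground truth echo the generative parameters directly.

### What passing tests do and do not show

The phantom establishes that the *pipeline* is correct: unit contracts,
oracle equivalence, exact offset cancellation, recovery of generative
quantities within 2 % (noiseless) / 5 % (1 cm/s noise), scaling laws, and
calibrated cohort emulation within 10 % at n = 30/group. It does not
validate performance on real data: real atria are not ellipsoids, real
velocity fields have coherent vortical structure and pulmonary-vein jets,
segmentation error is spatially correlated, and phase wrap, partial-volume
and acceleration artefacts are absent. Voxelized landmark volumes carry a
~1–1.5 % surface-voxelization bias at the default resolution, which the 2 %
recovery margin absorbs.

## Numerical choices and degenerate inputs

- Monotone piecewise-cubic (PCHIP) interpolation for volume curve, speed
  envelope, and strain profile: guarantees landmark values are attained and
  extrema are not overshot; flat derivative at extremum knots keeps sampled
  extrema second-order accurate.
- Degenerate motionless atrium (all landmarks equal) yields a constant
  curve and zero function; identical raters yield ICC = 1 with a collapsed
  CI; an all-zero paired difference returns p = 1 by convention, a
  constant nonzero shift p → 0.
- Mask resampling ties break toward the earlier frame, and equality checks
  on window membership use half-open intervals, so results are invariant
  to representable-time jitter.
- The offset fit raises on < 16 stationary voxels or a coplanar design
  rather than returning an ill-conditioned plane.
- Problem sizes in tests and the acceptance script (34 × 32 × 32 grids,
  25 flow / 30 cine frames, 30 subjects per group) were chosen as the
  smallest sizes at which voxelization error is comfortably inside the
  recovery margins.

## Known limitations

- The stasis temporal semantics ambiguity is resolved by configuration,
  not by evidence about the original implementation.
- Whether the original offset fit was per-slice or per-volume is unknown;
  only the global fit is implemented.
- The envelope-contrast compression (0.6) trades per-window velocity
  realism for joint calibration of mean velocity, stasis, and indexed KE.
- LAA metrics inherit the lobe's small voxel count (~100 voxels at default
  resolution); its stasis is a few percent noisier than the LA's.
- Strain ground truth is prescriptive (contours are generated from the
  strain curve), so strain tests validate the arithmetic and phase logic,
  not tracking robustness.
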