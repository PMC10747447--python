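# Methods

This note documents the measurement model, the conventions and defaults,
the synthetic data the package is validated on, and the numerical choices —
in the order the pipeline runs.

## Coordinate conventions

World frame: right-handed, Z up, meters; the floor is the plane Z = 0.
Camera frame: x right, y down, z forward (optical axis); pixels have their
origin at the top-left corner, x right, y down, so projection is
`K [R | t]` with `K` the intrinsic matrix, `R` the world-to-camera rotation
(orthonormal, det +1, checked to 1e-9) and `t` the camera-frame
translation.  No lens distortion is modeled; the camera type carries an
empty `distortion` hook so calibrated distortion could be added without an
interface change.

## Multi-view triangulation

Each 3D keypoint is reconstructed per frame by the direct linear transform:
every observing camera contributes the two rows
`x·m3 − m1` and `y·m3 − m2` of the homogeneous constraint on the world
point, and the stacked system is solved by SVD (right singular vector of
the smallest singular value, dehomogenized).

Conditioning: pixels are first mapped to normalized image coordinates
(`K⁻¹` applied per view) and the rows are built from the pose-only
projection `[R | t]`, then scaled to unit norm.  With known calibration
this plays the same centering-and-scaling role as the usual normalization
of the raw pixel system and keeps the design matrix well conditioned.

Diagnostics and edge cases:

* **Residual** — every point carries the RMS reprojection residual (px)
  over its contributing views; the per-frame mean is logged and written to
  the 3D CSV.
* **Degenerate geometry** — when the ratio of the two smallest singular
  values exceeds 0.9 the viewing rays are near-parallel and the solution is
  ambiguous; the point is kept but flagged, never silently invented.
* **Missing data** — a keypoint needs at least `min_views` (default 2)
  finite observations in a frame; otherwise it propagates as missing.  No
  temporal inpainting is done at this stage.
* Fewer than two observations, or cameras with coincident centers, raise.

The linear solution is oracle-checked in the tests against a nonlinear
least-squares minimizer of the summed squared reprojection error
(`scipy.optimize.least_squares` started from the linear estimate): at 1 px
noise the linear RMS is within 5% of the minimizer's and the points agree
to millimeters.  With zero noise the reconstruction is exact to < 1e-9 m.

## Joint angles

All angles are computed per frame, independently, with no smoothing.

**Torso frame.** Z is the unit vector from the reference hip (the right
hip, which anchors the keypoint set) to the neck.  X is the unit normal of
the plane through the two shoulders and that hip, computed as
`(shoulder_L − hip) × (shoulder_R − hip)` — left shoulder first, which
fixes the handedness — and then re-orthogonalized against Z: the neck is
not constrained to lie in the shoulder–hip plane, so the raw normal can
have a small component along Z, and the Gram–Schmidt step guarantees an
orthonormal frame to 1e-9.  Y = Z × X completes the right-handed triad.

**Hip flexion/extension** is the angle between −Z and the femur vector
(hip → knee), unsigned in [0°, 180°]: 0° is the anatomically neutral
stance, and the angle grows with the leg raised in *any* plane — the
definition is deliberately plane-agnostic, so the posterior-lateral
Y-balance reach uses the same formula as sagittal flexion; task metadata,
not a sign, records that it is an extension movement.

**Knee flexion** is the angle between the femur (hip → knee) and tibia
(knee → ankle) vectors, 0° when fully extended.

**Trunk side-bending** is the signed elevation of the shoulder line
(right shoulder → left shoulder) over the floor plane:
`atan2(vertical drop of the left shoulder, horizontal extent)`, positive
when the left shoulder is lower (a bend to the subject's left).  It
references the world floor rather than a pelvis frame, mirroring how a
shoulder-line-based markerless estimate differs from a spine-marker
measurement; consequently it is invariant under floor-preserving rigid
motions (yaw + horizontal translation) but not under arbitrary 3D
rotations, which the tests respect.

Numerics: angles between vectors are evaluated as `atan2(|u×v|, u·v)`
rather than `arccos` of the clamped dot product.  The two are identical on
[0°, 180°], but `arccos` loses half the significant digits near 0° and
180° (≈1e-6° error), while the `atan2` form keeps full precision
everywhere — this is what makes the generator round-trip contract (below)
hold to 1e-9°.  Dot products are still clamped to [−1, 1] so no NaN can
arise from rounding.

Degenerate inputs (coincident points, vertical shoulder line, collinear
shoulder–hip triple) raise a dedicated error; inside a series they yield a
missing sample instead, and the trace continues.

## Synthetic paired sessions

The generator emulates a concurrent-validity capture: one subject performs
a movement while a low-rate markerless rig and a high-rate reference system
record simultaneously.

* **Motion profile** — a raised-cosine rise to the peak angle, a plateau,
  and a mirrored return to 0°, parameterized by peak (deg), duration (s),
  rate (Hz) and hold fraction.  Defaults: 40° peak, 5 s, 12 Hz capture,
  hold 0.2 — an unhurried single repetition of a trunk side-bend of
  typical active range, slow enough for a 12 Hz system to resolve.  The
  profile is smooth and single-extremum so the max–min section of a trace
  is well defined.
* **Skeleton** — seven named keypoints (neck, both shoulders, both hips,
  right knee, right ankle) on a segment model approximating a 1.75 m
  adult: torso 0.50 m, shoulder half-width 0.18 m, hip half-width 0.10 m,
  femur 0.45 m, tibia 0.43 m, pelvis 0.95 m above the floor.  The keypoint
  set is configurable but must contain these seven names.
* **Forward kinematics** — constructed to be *exactly* consistent with the
  angle definitions: the side dip rotates the upper body about the
  anterior axis through the pelvis (so the shoulder line makes exactly the
  driving angle with the floor), and the Y-balance reach swings the
  extended right leg in the sagittal plane away from the torso's −Z axis
  (so the hip-angle formula recovers the driving angle).  This round-trip
  (generate → extract) is a tested contract at 1e-9°; it is what lets the
  end-to-end pipeline be graded against known ground truth.
* **Camera rig** — `n` cameras (default 4; any n ≥ 2, e.g. 5) evenly
  spaced on a 3 m ring at 1.2 m height, all aimed at the pelvis; 1000 px
  focal length, 1920×1080 image.  The subject stays fully in view in all
  default configurations.
* **Noise** — i.i.d. Gaussian pixel noise on every projected coordinate
  (default σ = 1 px, a typical pose-detector jitter at this image scale);
  the reference trace is the true angle plus independent Gaussian noise
  (default σ = 1°) and an optional constant offset, modeling the
  systematic discrepancy between a shoulder-line estimate and a
  marker-based measurement rather than the reference system's internals.
* **Determinism** — a single seed drives everything; per-repetition,
  per-camera and reference streams are split with
  `numpy.random.SeedSequence(entropy=seed, spawn_key=…)`, so identical
  configs give byte-identical outputs and repetitions are independent.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: no pose-detector outliers or identity swaps (the
noise is Gaussian, not heavy-tailed), no occlusion structure (missingness
arises only from leaving the camera frustum), no soft-tissue artifact, no
camera-calibration error, and no start/stop asynchrony between the two
systems (both records span the same physical interval).  Results on real
captures will be bounded by these effects, not by the pipeline's numerics.

## Temporal alignment

The two systems cannot be compared sample-by-sample (different rates,
manually operated start/stop in the emulated protocol), so pairing is
anchored on the movement itself:

1. One representative indicator defines the trial window: the span between
   its global maximum and global minimum (whichever comes first; ties break
   to the earliest index).  A constant indicator means no motion and is an
   error.
2. That window, expressed in normalized time, is applied to both traces.
3. Both sections are linearly resampled onto `n = 100` evenly spaced
   normalized times; endpoints are preserved exactly, and resampling a
   100-frame trace to 100 frames is a bit-exact identity.  Interior missing
   samples are bridged linearly with a logged warning.
4. Sign conventions are harmonized: a reference exported right-positive is
   negated to the left-positive convention; pairing different task families
   or signed-with-unsigned traces is an error.

The **representative defaults to the reference trace** and its window is
shared by both systems.  The alternative — each trace cut on its own
extrema (`representative="each"`) — is available but not the default, for
a concrete reason: a profile that starts and ends at the same value has
two near-tied minima, and measurement noise decides which end wins
independently in each system, so per-trace windows can select the rising
half of one record and the falling half of the other and destroy the
pairing.  Sharing one indicator's window, mapped through normalized time,
is also the natural automation of synchronizing two simultaneously started
recordings.  Linear (not spline) interpolation is used throughout: it is
monotonicity-preserving, and the agreement statistics are insensitive to
the choice of smooth interpolant at this grid density.

## Agreement statistics

The aligned pair forms an n × 2 table with the 100 normalized frames as
subjects and the two systems as raters — the only design under which a
per-trial ICC with a meaningful CI is computable from a single paired
trace.  On this table:

* **Two-way ANOVA** mean squares (MSR between frames, MSC between systems,
  MSE residual) from the exact one-observation-per-cell decomposition;
  SSR + SSC + SSE = SST is a tested conservation law.
* **ICC forms** (Shrout–Fleiss):
  * ICC(2,1) = (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n) — two-way
    random, absolute agreement; the default for concurrent validity
    because a constant offset between systems *should* lower it;
  * ICC(3,1) = (MSR − MSE) / (MSR + (k−1)MSE) — consistency, insensitive
    to a rater offset;
  * ICC(3,k) = (MSR − MSE) / MSR — average-measures consistency.
  95% CIs use the exact F-based bounds (McGraw & Wong), with the
  Satterthwaite degrees of freedom for ICC(2,1).  All three estimates and
  CIs are oracle-checked against pingouin to 1e-9.  A table with zero
  between-subject variance has no defined ICC and raises rather than
  returning 0; a perfect table (MSE = MSC = 0) returns exactly 1 with a
  point CI, avoiding 0/0 in the df formula.
* **Method-error CV** (%): Dahlberg form by default,
  `100 · (SD_d/√2) / |grand mean|` with SD_d the sample SD of the paired
  differences; the `literal` variant `100 · SD_d / |X̄₁ + X̄₂|` evaluates
  the formula exactly as it is sometimes printed (without the √2) for
  fidelity audits.  The denominator is taken in magnitude so the CV stays
  non-negative for signed traces with negative means (a side dip to the
  right).
* **SEM** = SD · √(1 − ICC) by default; the `literal` variant SD · (1 − ICC)
  again mirrors a radical-free printed form.  SEM is exactly 0 iff ICC = 1.
* **MDC95** = 1.96 · √2 · SEM ≈ 2.7718 · SEM, the smallest change
  distinguishable from measurement error at 95% confidence.
* **Interpretation bands** — default scheme: < 0.4 poor, 0.4–0.6 normal,
  0.6–0.75 good, ≥ 0.75 very good (boundaries go to the upper band); an
  alternative methods-style scheme (< 0.50 poor, 0.50–0.75 moderate,
  0.76–0.90 good, > 0.90 high) is selectable.

Report rows carry M and SD pooled over both systems' 200 values by default
(`pooled_descriptives=False` restricts them to the test system), then the
ICC with CI, CV, SEM, MDC95 and the band label, in a stable column order.

## Problem sizes and expected numbers

The default validation study is 5 repetitions of the 40° side dip: 61
camera-side frames × 7 keypoints × 4 views per repetition, 501 reference
samples, aligned to 100 frames.  Under the default noise it yields
ICC(2,1) ≈ 0.997–0.998 per repetition, CV ≈ 2–3%, SEM ≈ 0.6–0.8° and
MDC95 ≈ 1.7–2.1°.  With all noise off the pipeline reproduces the
camera-clock ground truth to ~1e-13° (triangulation exactness), while the
12 Hz vs 100 Hz cross-rate comparison is limited by linear-interpolation
error, bounded by max|θ″|·h²/8 ≈ 0.043° for the default profile — which is
why zero-noise recovery is asserted on the camera clock and the cross-rate
difference against its analytic bound.

## Known limitations

* The side-bend angle needs the world Z axis to be the true vertical; a
  tilted rig calibration would bias it (no gravity re-estimation is done).
* Linear DLT is not the maximum-likelihood triangulation under pixel
  noise; the tests show the gap is < 5% in reprojection RMS at 1 px noise,
  but heavy noise or near-degenerate rigs would widen it (no bundle
  adjustment, by design).
* Alignment assumes both records span the same movement once; multi-cycle
  trials would need cycle segmentation before pairing.
* The frames-as-subjects ICC treats normalized frames as exchangeable
  subjects; autocorrelation along the trace is ignored, as is standard for
  this design, so the CI width should be read as within-trial, not
  between-subject, uncertainty.
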