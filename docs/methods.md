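# Methods

## Angle geometry

All geometry operates on image pixels, origin top-left, y down. Sagittal
ROMs (hip flexion/extension, knee flexion) are the supplement β = 180° − α
of the law-of-cosines interior angle α at the measured joint; hip rotation
is θ = arctan(|Δx| / Δy) from the knee–ankle segment against the image
vertical. Consequences worth keeping in mind:

* β and α live on a triangle, so sagittal angles are invariant under
  translation, rotation and uniform scaling of the pixel coordinates —
  camera roll does not bias them.
* θ references the image vertical and is *not* rotation-invariant: the
  camera must be level. The test suite asserts this asymmetry explicitly.
  Whether a deployment should calibrate θ against a participant-specific
  neutral frame instead of the true image vertical is a protocol choice;
  this package measures from the true vertical.
* The arccos argument is clamped to [−1, 1] only within 1e-12; a larger
  excursion indicates broken inputs and raises. Coincident keypoints and an
  ankle at or above the knee are hard errors, not clamped values — they
  indicate tracking failure and silently "correcting" them would leak
  nonsense into a study table.
* Near 0° and 180° the arccos loses roughly half the floating-point digits
  (errors up to ~1e-6 degrees); irrelevant at whole-degree resolution but
  visible in raw-angle assertions, whose tolerance is 1e-5.

Rounding: app outputs are whole degrees, reference readings 1° intervals;
both round to nearest with ties away from zero, matching how a clinician
reads a goniometer scale. No temporal smoothing is applied — each frame is
measured independently, and saving a measurement is an explicit act.

Rotation direction convention (a labelling choice the magnitude does not
depend on): left leg viewed frontally, ankle toward image right of the knee
⇒ inner rotation, toward image left ⇒ outer; mirrored for the right leg; a
perfectly vertical shank has magnitude 0 and no direction.

## Reference-picture method

The reference measurement re-uses the identical geometry on operator-placed
bony landmarks (greater trochanter, lateral femoral epicondyle, humeral-head
midpoint, lateral malleolus, patella midpoint, talocrural centre). A property
test asserts the two methods agree exactly on identical coordinates: any
observed app-vs-reference disagreement is attributable to *where* the points
are, never to the math. Landmarks are entered as a CSV of named pixel
positions; no GUI annotator is included, keeping the package headless.
Bony landmarks sit at an offset from a detector's joint centres; the study
generator exposes a constant landmark offset (default 0 px) so users can
probe the systematic bias this induces.

## Reliability and validity statistics

ICC: single-measure, absolute-agreement, two-way random effects —
ICC(2,1)/ICC(A,1) — computed from the ANOVA mean squares
(MSR between subjects, MSC between sessions, MSE residual; k = 2):

    ICC = (MSR − MSE) / (MSR + MSE + 2(MSC − MSE)/n)

The absolute-agreement form is used because SEM is an absolute-reliability
quantity; a consistency variant (ignores session offsets) is available via
`form="consistency"` for sensitivity checks. The 95% CI follows the
McGraw–Wong F-distribution method; the implementation is cross-checked in
tests against an independently coded brute-force ANOVA oracle (1e-12) and
against pingouin's ICC(A,1).

SEM = S√(1 − ICC) with S the sample SD (denominator 2N−1) of the pooled 2N
scores; a per-session-mean alternative for S is available behind
`s_mode="session_mean"`. MDC = SEM·√2·1.96 = 2.7718586·SEM. Degenerate
cases: identical sessions return ICC = 1 with a degenerate CI; a zero-variance
table raises rather than returning 0/0.

Ordinal labels (lower bounds inclusive, bands as printed to two decimals):
ICC ≥ 0.81 almost perfect, ≥ 0.61 substantial, ≥ 0.41 moderate, ≥ 0.21 fair,
else slight; |r| ≥ 0.90 very strong, ≥ 0.70 strong, ≥ 0.50 moderate, ≥ 0.30
weak, else very weak. A negative ICC is labelled slight with a warning.

Bland–Altman: differences are taken app − reference (so an app that reads
low yields a negative bias), limits of agreement bias ± 1.96·SD(d) with the
n−1 SD, and outliers are differences *strictly* outside the limits.

## Synthetic data

The generator emulates the standardized protocol: 30 participants, two
sessions 24 h apart, five movements in fixed order (hip flexion, knee
flexion, hip extension, hip inner rotation, hip outer rotation), one app
measurement per session and one reference measurement on the session-1
frame.

Projection: pinhole camera, focal length from the horizontal FOV, lens
55 cm above the floor and 2.05 m from the participant plane, 1280×720. The
default FOV is 78° — typical of integrated laptop webcams and the geometry
needed for a standing 177.5 cm adult's shoulder to stay inside the frame at
this distance (≥ 73° is required; narrower cameras raise a framing error
suggesting a config change). Because the skeleton is posed in a
fronto-parallel plane, the projection is a similarity transform and posed
angles survive projection exactly; this is why the project→measure round
trip is exact to rounding, which the tests exploit on a 5° grid over each
movement's anatomical range (hip flexion 0–130°, extension 0–40°, rotations
0–60°, knee 0–150°).

Anthropometry: segment lengths as fixed stature fractions (trunk 0.30,
thigh 0.245, shank 0.246; stature default 177.5 cm). Rotation postures tilt
a fixed-length shank in the frontal plane — a 2D proxy for rotation about
the femoral axis, which is exactly the quantity the frontal-view right
triangle measures.

Study model: participant true angle θ_i ~ N(μ, σ_b²); session value
θ_is = θ_i + N(0, σ_w²); draws outside the anatomical range are resampled
(counted; > 1% triggers a warning, since heavy truncation distorts the
variance components). The app measurement is the rounded measurement of the
projected frame after iid Gaussian keypoint noise N(0, σ_px²) per
coordinate; the reference measurement applies landmark placement noise
(σ default 2 px) and the optional constant offset to the *noiseless* frame.
The theoretical ICC σ_b²/(σ_b² + σ_w² + σ_meas²) is recorded in the ground
truth, with σ_meas (the angle-domain noise induced by σ_px) estimated by
Monte Carlo at the population-mean posture.

Default movement populations (μ, σ_b in degrees): hip flexion (105, 10),
knee flexion (125, 8), hip extension (18, 5), inner rotation (35, 8), outer
rotation (40, 8) — anatomically plausible active ROMs for healthy young
adults measured standing, chosen as documentation/testing values, with
σ_w = 3° and σ_px = 1 px as defaults. All randomness flows through one
`numpy` generator seeded from the config, so identical config + seed gives
bit-identical studies; simulated timestamps are derived from a fixed epoch
for the same reason.

What the generator does *not* emulate: detector noise is iid Gaussian,
whereas real HPE keypoints show heavy tails, temporal correlation and
occlusion dropouts; landmark placement error is isotropic, whereas raters
err anisotropically along bone axes; anthropometry is a single standing
stick figure. Passing tests therefore demonstrate the correctness of the
geometry and statistics under known variance components — not the field
accuracy of any particular pose detector.

## Problem sizes

The test suite and acceptance script use 10⁴ random configurations for the
geometry-oracle comparison, 200 replicate 30-participant single-movement
studies for ICC recovery and CI coverage, and 10⁵ Normal draws for
limits-of-agreement coverage; the full default study is 30 participants ×
2 sessions × 5 movements × 2 methods. These sizes give Monte-Carlo error
comfortably below the assertion tolerances (e.g. binomial SE ≈ 1.5% for CI
coverage at 200 replicates) while the whole suite runs in seconds.

## Known limitations

* 2D projection only: out-of-plane limb motion foreshortens segments and
  biases sagittal angles; the generator's fronto-parallel assumption is the
  best case.
* The rotation measure conflates hip rotation with any lateral shank sway.
* ICC forms with > 2 raters/sessions, non-parametric agreement and
  regression-based limits of agreement are out of scope.
* The blinding guard in the CLI compares file modification times, which is
  a workflow heuristic, not cryptographic provenance; it can be disabled
  with `--no-blind-check`.
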