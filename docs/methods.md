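# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `kinemetrics`.

## Input model and confidence filtering

The pipeline ingests per-frame 2D keypoints for 12 limb joints (bilateral
shoulders, elbows, wrists, hips, knees, ankles) with a detection confidence
in [0, 1], as produced by COCO-17 pose estimators. Face keypoints are never
read. Frames are kept on a contiguous grid; recording gaps appear as missing
frames. Observations with confidence strictly below the threshold (default
0.5) are treated as measurement errors and removed — a confidence of exactly
0.5 is retained. When a frame contains several detections, the one with the
highest mean limb-joint confidence is kept (configurable; supine single-
infant recordings rarely need it).

Data adequacy is report-only: a joint passes if its missing fraction is at
most 0.30, and a recording passes if it is at least 120 s long. Both bounds
are configuration values, not hard-coded; they encode the usual
at-least-two-continuous-minutes recording convention at the data level.
Pose files do not carry a frame rate, so it must be supplied (default
30 fps).

## Joint angles

Each of the 8 angle-bearing joints carries the interior angle at the joint
between the rays to two adjacent joints:

| joint    | adjacent joints                               |
|----------|-----------------------------------------------|
| shoulder | contralateral shoulder, ipsilateral elbow     |
| elbow    | ipsilateral shoulder, ipsilateral wrist       |
| hip      | contralateral hip, ipsilateral knee           |
| knee     | ipsilateral hip, ipsilateral ankle            |

"Adjacent" is read as ipsilateral for the elbow and knee. The angle is
computed as atan2(|u x v|, u·v), numerically stable near 0° and 180°, and
lies in [0°, 180°]. Interior angles are invariant to translation, rotation,
uniform scaling and reflection of the image, so camera distance, framing and
mirroring cannot affect them — the reason angles, not raw coordinates or
segment lengths, are the kinematic primitives. An angle is defined at a
frame only if all three keypoints survived filtering.

## Smoothing and interpolation

Missing-data repair and noise reduction are one step: single-pass locally
weighted linear regression (tricube weights) over frame time, evaluated at
every frame. The span (window width as a fraction of frames) defaults to
0.05 — about 9 s for a 3-minute recording — chosen as a conservative default
in the absence of an established bandwidth for infant limb kinematics; it is
configuration-exposed and stamped into reports. One pass (no robustness
iterations) keeps the operation deterministic and fast. Local *linear*
fitting reproduces linear trends exactly regardless of the missing pattern,
which the tests exploit as an oracle.

Implementation: the fit at observed frames uses the standard lowess `delta`
shortcut (anchor fits at most 1% of the time range apart, linear
interpolation between anchors — exact on locally linear data); missing
frames are always evaluated with the full local regression. Output is
clipped to [0°, 180°]; an overshoot beyond 0.5° triggers a warning. A joint
needs at least 4 observed points and a 4-frame window, otherwise smoothing
fails for that joint and the joint is flagged (never silently dropped).

Angular velocity is the symmetric difference quotient of the *smoothed*
angle, ω[t] = (θ[t+1] − θ[t−1])·fps/2, in degrees per second (units are
explicit because per-frame differences would silently depend on frame
rate). The two endpoint frames are undefined. The scheme is second-order
accurate; tests verify the ~4x error reduction when the sampling interval is
halved.

## Sample-entropy complexity indices

SampEn(m, r, N) = −ln(A/B) with B the number of unordered pairs (i < j,
self-matches excluded) of length-m template vectors within Chebyshev
distance r, and A the same count at length m+1, both over the first N − m
start indices so the ratio is a conditional probability. Conventions that
matter and are mirrored exactly by the brute-force oracle in the tests:
distance ≤ r counts as a match; each unordered pair is counted once; the
tolerance is r = r_factor · sd(series) with the population sd (so SampEn is
scale-invariant); a constant series returns 0 with a warning (r would be 0
but every template matches); if no pair matches at either length the index
is undefined (NaN, never an exception).

Defaults m = 2, r_factor = 0.2 — the standard setting for physiological
series of this length — are configuration values recorded in every report.
SampEn is computed on the full smoothed angle series and on the velocity
series with its endpoint NaNs dropped; an optional uniform-decimation length
cap exists but is off by default. The production kernel is a compiled
O(N²) pair count (numba when available, vectorized numpy otherwise — results
identical, verified in tests).

## Similarity indices

Inter/intra-limb synchronization is the Pearson correlation between two
joints' angle series (and, separately, velocity series), computed over
frames observed in both (pairwise deletion, since missingness is per-joint),
by default on the smoothed series. All 28 unordered pairs of the 8 joints
form a symmetric 8×8 matrix with unit diagonal. At least 3 complete pairs
are required; zero variance makes an entry undefined. Narrative strength
labels use the conventional bands |ρ| < 0.20 very weak, 0.20–0.39 weak,
0.40–0.59 moderate, 0.60–0.79 strong, ≥ 0.80 very strong (configurable —
no canonical banding exists).

## Cohort statistics

Infants are grouped at the HINE global-score cut of 60 (< 60 = risk group;
the boundary belongs to the high group). Continuous indices are compared
two-sidedly with Student's t (equal variances) or Mann–Whitney U; in `auto`
mode t is used only when both groups pass Shapiro–Wilk at α = 0.05. For the
cohort-characteristics table the continuous default is Mann–Whitney.
Categorical 2×2 tables use Pearson chi-squared *without* continuity
correction unless an expected cell is below 5, then Fisher's exact
(two-sided); correction-free chi-squared is the convention that reproduces
published cohort-table p-values from their own counts. Index–outcome
association is Pearson's r with the two-sided p from the t distribution on
n − 2 df. Every result records the method used. No multiple-testing
adjustment is applied by default (α = 0.05 per test); a Benjamini–Hochberg
helper is available but off.

Degenerate inputs are handled explicitly: identical values across both
groups give p = 1 with a warning; zero table margins give an undefined
result; single-record cohorts report sd = 0 with a flag.

## Synthetic cohort generator

The generator exists so the whole pipeline can be validated against known
ground truth; no pipeline stage reads the truth object.

**Angle model.** θ(t) = midline + A·z(t), z the standardized mixture
(1 − λ)·sin(2πft + φ) + λ·s(t), with per-joint frequency f ~ U(0.03, 0.06) Hz,
random phase, amplitude A = 18° RMS around a 90° midline, and s(t) a
smoothed AR(1) process (time constant 0.5 s, frame-rate-free) scaled to unit
sd. The irregularity λ ∈ [0, 1] is a *mixing weight*, not a noise variance:
because the SampEn tolerance scales with the series sd, irregularity must be
tunable at constant amplitude. The deterministic oscillation is deliberately
slow relative to the stochastic component: after the default 9-s smoothing
window, the irregular content is also the relatively fast content, which
makes measured SampEn increase monotonically with λ (the design requirement).
An early variant with a 0.08–0.16 Hz oscillation inverted this relationship
— slow stochastic wander is *more* template-predictable than a faster sine —
which is why the time-scales are part of the design, chosen once and fixed.

**Coupling.** For each configured joint pair, the standardized drives are
mixed as z_b ← κ·z_a + √(1−κ²)·z_b, giving corr ≈ κ. Default: ipsilateral
hip–knee κ = 0.9 on both sides, mirroring the strong hip–knee
synchronization of infant kicking; all other pairs uncoupled.

**Skeleton and detection noise.** A static, bilaterally symmetric torso
(shoulders/hips in pixels, y-down) anchors forward kinematics that place
elbow, wrist, knee and ankle so the pipeline's angle definitions recover
each scripted angle exactly (left-side rotations mirror right-side ones, so
identical bilateral scripts yield exact reflections). Gaussian pixel jitter
(sd 1 px) is added, and confidences come from a two-state Markov model:
clear frames ~ Beta(8, 2), occluded runs (geometric lengths, mean 0.4 s)
~ Beta(2, 8); the occupancy is solved so the marginal fraction of
observations below confidence 0.5 equals the configured dropout (default
0.05) — occlusion in real video is temporally clustered, not i.i.d.

**Outcome model.** Per-infant λ comes from a two-component mixture
(defaults 0.20 vs 0.75, sd 0.05, low fraction 16/65) and
HINE = 44.5 + 33·λ + N(0, 5.5), rounded and clipped to [0, 78], putting the
component means near 51 and 69 with a roughly 16/49 split at the cut of 60 —
the cohort structure the statistics layer is designed for. A covariate
(multiple gestations) is generated at different rates per component so the
cohort table exercises its categorical tests.

**What the generator does not emulate:** real pose-estimator error
structure (anisotropic, pose-dependent), anatomy and growth differences,
camera motion, non-stationary behavioural states (sleep/cry), or the actual
GMA movement categories. Passing end-to-end tests therefore demonstrates
that the *pipeline* recovers known kinematic structure from noisy keypoints
— not that the synthetic movements are biomechanically realistic.

## Validation scales

Tests validate at reduced problem sizes chosen for thorough coverage per
unit time; all are package design choices stamped in the tests themselves:

* module-level checks: series of 10²–10³ samples, exhaustive-enumeration
  oracles up to N = 300;
* end-to-end outcome recovery: 50 cohorts of 65 infants, 45-s recordings at
  20 fps, with the λ contrast (0.22 vs 0.32, sd 0.02; HINE slope 181,
  intercept 11.3) calibrated once so the angle-SE group gap is ≈ 0.02 at
  that scale — the same order as the group differences the method is meant
  to resolve; plus 200 zero-slope cohorts (30 s at 10 fps, intercept 60)
  verifying the nominal ~5% false-positive rate;
* `scripts/acceptance.py`: the full study design, 65 infants × 180 s ×
  30 fps.

Measured SampEn depends on sampling rate and duration, so per-scale
magnitudes differ; the calibration above is therefore scale-specific by
construction.

## Known limitations

* 2D only; out-of-plane motion projects onto the image plane and biases
  angles — inherent to single-camera input.
* The smoothing bandwidth trades noise rejection against attenuation of
  fast movement; the 0.05 default favours robustness and will damp genuine
  high-frequency jerks. Complexity indices are computed *after* smoothing
  and inherit this choice.
* SampEn on ~5 000-point series has sampling variability of a few
  thousandths; cohort-level contrasts, not single-infant values, are the
  intended readout.
* The t/Mann–Whitney auto gate and the chi-squared/Fisher expected-count
  gate are standard but not the only defensible rules; both can be forced
  per call.
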