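# Methods

`conjflow` measures microvascular hemodynamics from one-second grayscale
video of the bulbar conjunctiva (vessels dark on a bright background, the
standard green-light transmission appearance) and compares the resulting
per-vessel descriptors across stages of diabetic retinopathy.  This note
documents the models, the numerical choices, what the synthetic generators
emulate, and the limits of what the tests demonstrate.

## Acquisition model

Defaults mirror the acquisition the analysis was designed for: 50 frames/s,
one-second sequences, 1.25 µm/pixel on the object plane.  All three are
configuration (`AcquisitionConfig`), and every downstream unit conversion is
derived from them; nothing else about the instrument is modeled.

## Frame screening and registration

Frames are screened before registration:

* **blink** — robust z-score of the frame mean intensity against the
  sequence median (default |z| > 4); blinks darken the whole frame.
* **illumination** — a least-squares plane is fitted to the frame; frames
  whose fitted gradient span exceeds 20 % of the median intensity are
  dropped.
* **motion** — normalized cross-correlation with the previous valid frame.
  The default threshold is deliberately low (0.5): at fast flow the
  red-blood-cell texture inside vessels turns over completely between
  frames, which alone caps frame-to-frame NCC near 0.8 in texture-dominated
  fields.  The screen is meant to catch gross eye motion, not flow.

The longest consecutive run of valid frames is kept (ties go to the
earliest run) and registered by a single 2-D sub-pixel translation per
frame (phase cross-correlation, 1/20 px resolution).  Two choices matter:

1. **Shifts are estimated against the run mean, not a reference frame.**
   Correlating two raw frames can lock onto the moving cell texture rather
   than the static vascular pattern; the texture averages out of the mean.
   A second pass against the registered mean refines the estimate.
   Translations are then re-zeroed so the middle frame of the run — the
   reference — carries exactly (0, 0).
2. **Implausibly large shifts are reported, not applied.**  An estimated
   shift above 10 % of the frame width means the correlation failed; the
   frame is listed in the output and left unshifted rather than being
   allowed to corrupt the time-averaged image.

The registration model is translation-only: over one second, eye motion at
this field size is dominantly translational, and no rotation/scaling is
attempted.  Borders invalidated by shifting are edge-replicated and masked
out of downstream analysis (`valid_mask`).

On scenes that contain only a single straight vessel the x-component of the
translation (along the vessel) is weakly constrained and the moving texture
can bias it by up to ~1 px; with two or more vessel orientations in the
field — the realistic case — injected jitter is recovered to better than
0.5 px.

## Segmentation, centerlines, and the 50 µm rule

The time-averaged image is lightly denoised (Gaussian, σ = 2 px), and
Frangi vesselness is computed for dark ridges over eight log-spaced scales
σ = 1–30 px, covering vessel radii for the 6–75 µm measurable range at
1.25 µm/px.  The mask is vesselness above 0.1 × Otsu (taken over nonzero
vesselness), followed by: small-object removal, morphological closing
(disk 3) and hole filling (wide vessels have flat intensity cores where
vesselness dips), outline regularization (Gaussian of the binary mask,
σ = 3 px, re-thresholded at 0.5), and a 2 px dilation to recover the outer
tube footprint.  The regularization step exists because the medial axis of
a wiggly-outlined wide mask fragments into dozens of spurious branches.
All parameters live in `SegmentationConfig`.

The mask is thinned to an 8-connected 1-px skeleton.  Spurs are removed by
walking from each endpoint: if a bifurcation (≥ 3 neighbours) is reached
within 30 px the twig is deleted; free ends of unbranched centerlines are
never eroded.  The skeleton is cut at bifurcation pixels; each remaining
path is one vessel segment, its arc length the sum of 1/√2-pixel steps
times the pixel size.  Segments of 50 µm or less are discarded (strict
inequality — "above 50 µm").  Each segment remembers its parent skeleton
component so that multiple segments of one vessel can be de-duplicated
later by keeping the longest centerline (ties: more diameter stations, then
lowest segment id).

## Diametry (FWHM)

Diameters are measured on the time-averaged image at stations every 5 px of
arc length along the smoothed (σ = 2 px) resampled centerline.  At each
station an intensity profile is sampled perpendicular to the local tangent
(bilinear interpolation, half-length 60 µm, step 0.5 px), inverted, and
referenced to the median of its outer 25 % tails; the diameter is the
distance between the two half-maximum crossings found by linear
interpolation outward from the deepest point.  Stations whose profile
leaves the image, shows less than 2 % contrast against its background, or
lacks two crossings are dropped; a segment with fewer than 3 valid stations
is rejected ("diametry failed").  Only segments with mean D inside
6–75 µm are admitted to hemodynamic analysis.

On rendered vessels with analytically known FWHM the mean absolute error
across D ∈ {6, 10, 20, 40, 60} µm is ≈ 0.3 µm at zero noise and ≈ 0.3 µm at
5 % noise (bounds asserted: 1.25 µm and 2.5 µm).

## Flow detection

A segment is flagged as carrying detectable flow when the mean temporal
intensity variance along its centerline exceeds twice the background
variance (median temporal variance outside the dilated vessel mask).  A
static noiseless scene has exactly zero variance and is never flagged; the
2× factor keeps false detections on stagnant vessels in noisy sequences at
the few-percent level.

## Velocimetry (kymograph band slope)

For each flow-detected segment the registered stack is sampled along the
centerline at 1 px arc steps into a (stations × frames) kymograph, then
two-way mean-detrended (row and column means removed).  Moving cells form
oblique bands; the axial speed is

    V [mm/s] = |slope| · arc_step [µm] / frame_interval [s] / 1000,

with slope in px/frame.  The slope is found by a projection (Radon-
criterion) search: for each candidate slope the kymograph is sheared so
that candidate bands become horizontal rays, and the candidate is scored by
the ANOVA F-ratio of between-ray to within-ray mean squares.  Two details
are deliberate:

* **The search grid is uniform in slope, not angle.**  The score peak has
  roughly constant width in slope units (texture correlation length divided
  by the frame count), so a uniform angle grid undersamples steep bands:
  at 3 mm/s the slope is 48 px/frame where a 0.25° angle step spans ~10
  px/frame.  A coarse grid (0.2 px/frame, capped at the aliasing ceiling
  |slope| < (stations−1)/2) is refined by a 25× finer local grid and
  parabolic interpolation.
* **The F-ratio score is envelope-free.**  A raw variance of ray means is
  normalized by the ray count, which itself grows with |slope|; that
  envelope biases estimates low by ~2 % on 120-station kymographs.  The
  F-ratio's expectation under white noise is flat in slope; residual bias
  is ≤ 0.6 % at 120 stations.

The quality score is (max − median)/median of the F-scores over the coarse
grid; estimates below 6.0 are flagged unreliable.  The floor was calibrated
on white-noise kymographs (97.5th percentile ≈ 5.3) against genuine bands
at signal-to-noise 1 (scores ≥ 13).  Recovered speed is reported as a
magnitude; the sign of the slope is kept for flow-direction annotation.
Across 0.1–3.0 mm/s on rendered scenes the relative error is ≤ 2.5 %
(bound asserted: 5 %).

## Hemodynamic descriptors

With D in µm, V in mm/s and subject hematocrit HCT:

* Vs = V / k, k = 1.6 by default — the axial-to-mean velocity conversion
  for microvessels with blunted (non-parabolic) profiles; configurable
  because different conversions are defensible for different vessel sizes.
* Q = Vs π D²/4 (Vs in µm/s; Q reported in pl/s, 1 pl = 1000 µm³).
* WSR = 8 Vs / D (Vs in µm/s) in s⁻¹ — the Poiseuille wall shear rate.
* η = η_plasma · η_rel(D, HCT), η_plasma = 1.2 mPa·s by default, with the
  in-vitro diameter-dependent relative-viscosity law (Fåhræus–Lindqvist
  effect):
  η_rel = 1 + (η*₀.₄₅ − 1)·((1−HCT)^C − 1)/((1−0.45)^C − 1),
  η*₀.₄₅ = 220 e^(−1.3D) + 3.2 − 2.44 e^(−0.06 D^0.645),
  C = (0.8 + e^(−0.075D))(−1 + 1/(1+10⁻¹¹D¹²)) + 1/(1+10⁻¹¹D¹²).
* WSS = η · WSR · 0.01 in dyne/cm² (from mPa·s × s⁻¹).

Every emitted record is audited: recomputing Q, WSR and WSS from the stored
D, Vs and η must reproduce the stored values to 10⁻⁹ relative tolerance.
MAP = (SBP + 2·DBP)/3.  Subject-level hematocrit is used for all vessels of
a subject; no per-vessel hematocrit or Fåhræus reduction is modeled.

## Cohort statistics

Two granularities:

* **ANOVA** on per-subject mean descriptors (one value per subject per
  vessel type), giving the stratified mean ± SD summary and an F-test
  P-value across the four groups (C, NDR, NPDR, PDR).
* **Random-intercept linear mixed models** on vessel-level rows:
  y_ij = Xβ + b_i + ε_ij, b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_ε²), fitted by
  REML (statsmodels MixedLM) with Wald 95 % CIs and two-sided P-values,
  significance at P ≤ 0.05.  Group C is the reference level; adjusted
  models add age, race, sex, MAP, HR, HCT and HbA1c as fixed effects, with
  the largest observed category as reference for race and sex.  Rows with
  missing covariates are dropped and counted.  If the random-intercept fit
  is singular the model falls back to ordinary regression with a logged
  warning.  No multiple-testing correction is applied.

The V-on-D association uses the same random-intercept model with a
group × D interaction; each group's slope (base + interaction) is reported
in s⁻¹ (mm/s per µm × 1000) with a Wald CI, and the interaction Wald test
is the comparison of that group's slope to control.

Calibration on simulated cohorts: under a zero group effect the Wald test's
type-I error is 5 % ± 2 % and 95 % CI coverage is 95 % ± 3 % (500
replicates, 12 subjects/group × 6 vessels); an injected 0.16 mm/s velocity
deficit is recovered with |bias| < 0.02 mm/s (200 replicates, 40
subjects/group × 12 vessels).

## Synthetic generators

`render_sequence` draws dark tubes on a bright field.  The cross-section is
an inverted flattened-Gaussian, exp(−ln2 (2r/D)⁴), whose FWHM equals the
nominal diameter exactly, so diametry has an analytic target.  Each vessel
carries a frozen 1-D Gaussian-correlated texture (correlation length 10 µm
by default, amplitude ±50 % of the local contrast, clipped at ±1.8 SD)
advected along the centerline by exactly V·Δt/pixel-size per frame, so
velocimetry has an exact target.  Artifacts: whole-frame translational
jitter (explicit offsets or random integers), blink frames at 10 % of
background, per-frame or static illumination gradients, and i.i.d. Gaussian
sensor noise.  One seeded generator drives all randomness; rendering is
bit-reproducible.  Scenes whose per-frame displacement reaches half the
centerline length are rejected as aliased at construction.

What it does **not** emulate: depth-of-field blur, specular reflections,
vessel pulsatility, discrete single-cell gaps (texture is continuous),
non-rigid tissue motion, or tortuosity pathology.  Passing the imaging
tests therefore demonstrates correctness of the measurement chain under the
stated image model, not robustness to every property of clinical video.

`simulate_cohort` draws vessel-level descriptor tables with per-subject
random intercepts and Gaussian residuals, group offsets, and per-group
covariate distributions (age, MAP, HR, HCT, HbA1c, race/sex proportions)
matching a realistic four-group study population.  Default group sizes are
34/47/45/35 and default descriptor means are typical arteriolar/venular
values (e.g. venular D ≈ 20–21 µm, V ≈ 0.52–0.59 mm/s).  Within-subject D
residual SD defaults to 8 µm — per-vessel diameters span the whole 6–75 µm
detectable range — while per-subject mean D varies little (intercept SD
1.5 µm).  An optional per-group V-on-D slope (s⁻¹) couples V to D for the
slope analyses.

## Problem sizes used in the checks

The accuracy checks run on 232 × 356 px scenes (50 frames), a ~400 µm main
vessel plus an oblique anchor vessel; Monte-Carlo calibration uses
500/200 replicates in the test suite and 300/150 in the acceptance script
(replicate counts are recorded in the script's JSON output).  These sizes
were chosen so the full verification runs comfortably on a laptop-class
single core while keeping binomial error well inside the asserted bands.

## Known limitations

* Vessel type (arteriole vs venule) is a manual/ground-truth label by
  design; no automatic classifier is provided.
* Translation-only registration; rotational eye movement is not corrected.
* The velocity-profile factor k and the viscosity-law constants are
  conventions exposed in configuration, not quantities estimated from data.
* Velocity estimates are time-averages over the one-second window; cardiac
  pulsatility is not resolved or gated.
* The kymograph estimator needs ≥ 20 stations (25 µm) and ≥ 10 frames, and
  cannot measure speeds whose per-frame displacement approaches half the
  segment length (flagged as aliased).
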