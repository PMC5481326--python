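# Methods

This note documents the models, parameter choices and numerical
decisions behind `zfmask`, and what the synthetic-data tests do and do
not establish about real recordings.

## Stimulus schedules

A schedule is a contiguous, non-overlapping tiling of the recording by
60 s epochs. The behavioral layout is `n` cycles of darkness followed by
light of one channel (blue 470 nm, green 525 nm, red 660 nm or UV
375 nm); the imaging layout interleaves 60 s dark epochs with blue or
red 60 s pulses in seeded random order with equal counts per color,
which is why an even pulse count is required. Default irradiances are
photon-matched across channels at ≈1.5 × 10¹⁵ photons·cm⁻²·s⁻¹
(blue 650, green 580, red 465, UV 826 µW/cm²), because photoreceptor
activation counts photons rather than energy; direct evaluation of
`I = (P/A)/(hc/λ)` for these settings gives 1.53–1.55 × 10¹⁵, about
1.5% below the conventionally quoted ~1.56 × 10¹⁵ — we report the
unrounded CODATA-constant value.

## Behavior model

Depth follows a first-order drift–diffusion process in a 5.0 cm water
column (0 cm at the surface, increasing downward — the convention every
module shares). Per epoch and fish, a Bernoulli draw with probability
equal to the channel's *responsiveness* decides whether the fish
responds; a responder drifts at a per-epoch speed drawn from
N(0.08, 0.02²) cm/s toward the epoch-congruent end (up in light, down in
darkness), a non-responder performs a pure random walk. Diffusion adds
N(0, σ²·dt) increments with σ = 0.08 cm/√s; positions clip to [0, 5].
Dark epochs take the responsiveness of the adjacent light epoch's
channel: the dark-phase dive is the other half of the same
wavelength-dependent response, and a standalone `dark` responsiveness is
pinned to zero.

Defaults (blue/green 0.85, red 0.25, UV 0.15) were chosen so a
blue-light group crosses the half-depth mark in roughly 75–90% of
fish × cycle events, the range reported for the assay at standard
irradiance; with crossing requiring both a dive in the previous epoch
and a response in the current one, responsiveness 0.85 yields occurrence
near 88/120. The model deliberately omits fluid dynamics, body posture,
horizontal motion and any trial-to-trial adaptation; passing tests
therefore show the *statistics* behave correctly on trajectories with
the right coarse structure (sawtooth-like migration, boundary clipping,
between-fish variability), not that the model predicts real larval
kinematics.

One consequence worth knowing: unresponsive fish are bounded random
walks, and independent random walks exhibit large spurious pairwise
correlations. Group comparisons should therefore rest on the
matrix-equality test and the speed metrics, as the analysis battery
does, rather than on raw correlation magnitudes.

## Video rendering and tracking

The renderer draws one Gaussian blob (σ = 3 px, amplitude 200 over a
background of 10) per frame at the row given by the linear calibration
`depth = cm_per_px · row`, one fish per video as in the assay's
individual chambers. The tracker thresholds each frame, keeps the
largest connected component (reflections produce smaller secondary
blobs), and takes the intensity-weighted centroid above threshold for
sub-pixel precision — smoother speed estimates than a bounding-box
center. Frames with no component are linearly interpolated and flagged,
up to 5 consecutive frames (1 s at 5 fps); longer gaps, or more than 20%
missing overall, abort with an error because interpolated speed
estimates would dominate the 20 s analysis windows. Bright-fish-on-dark
polarity is assumed (IR illumination with a longpass filter); a flag
inverts it.

## Behavioral statistics

* **Initial speed** is net displacement over the first 20 s of an epoch
  divided by 20 s, signed positive in the epoch-congruent direction.
  Net displacement (rather than mean absolute frame-to-frame speed) is
  the quantity that distinguishes directed climbs/dives from agitation.
* **Final position** is mean depth over the last 20 s of the epoch.
* **Occurrence** counts epochs in which the fish crossed the 2.5 cm
  half-depth mark in the congruent direction; the crossing must happen
  within the epoch, so time-to-half is right-censored at 60 s.
* **Correlation matrices** are Pearson r of the full concatenated
  10-cycle traces, no detrending. Group comparisons of "correlation
  coefficients" use the upper-triangle values as the sample (66 values
  for 12 fish, 276 for 24).
* **Jennrich's test** uses the number of time samples per trace as the
  group sample sizes. Temporal autocorrelation of the traces violates
  the test's independence assumption and inflates the statistic; this
  is documented rather than corrected, and callers may pass a decimated
  sample count instead. A null calibration (independent Gaussian
  groups, p = 5, n = 500) verifies mean χ² ≈ df and a 5% nominal
  rejection rate.
* **Mann-Whitney U** is reported as min(U_x, U_y) with midrank ties; p
  is exact by enumeration when n₁+n₂ ≤ 20 without ties, otherwise the
  tie-corrected normal approximation with continuity correction. A
  one-tailed p is taken in the direction favored by the data. The
  rank-biserial effect size is reported as a magnitude, matching the
  convention of quoting |r| regardless of direction.
* **Bonferroni** divides α by the stated hypothesis count only (no FDR)
  and reports at 4 decimals (0.05/3 → 0.0167).

## Calcium-movie simulator

Each planted source is a truncated-Gaussian footprint paired with one of
five response classes: sustained blue, sustained red, transient at all
light onsets, transient at all light offsets, transient at blue offsets
only. Transients jump to 1 at the event and decay exponentially
(τ = 10 s default). The ideal drive is convolved with a unit-area
difference-of-exponentials indicator kernel (rise 0.1 s, decay 0.7 s —
GCaMP6f-like defaults, configurable; unit area preserves sustained
plateau amplitudes). Pixels get additive Gaussian noise; SNR means
amplitude/noise-SD. The noiseless movie is the exact analytic
superposition of the sources, which the decomposition tests exploit.
Simulation is single-plane; a volumetric acquisition is represented as
independent planes. No shot noise, bleaching, motion or neuropil
contamination is modeled — so the pipeline tests certify the algorithm,
not robustness to those artifacts.

## PCA/ICA decomposition

PCA operates on the mean-subtracted pixel-time matrix via an
eigendecomposition of the smaller Gram matrix (movies are long and
narrow, making this much faster than a full SVD at identical results).
Requests beyond the numerical rank (relative eigenvalue ≤ 1e-12) raise.
Components are sign-fixed by the positive-skew rule: a calcium source is
a bright blob on a flat background, so the correctly oriented spatial
map is positively skewed; near-symmetric maps fall back to temporal
skewness.

ICA is a symmetric fixed-point iteration with the skewness contrast
G(u) = u³/3 on the jointly whitened, μ-weighted concatenation of the
spatial and temporal component views. Defaults: μ = 0 (purely spatial —
footprints of distinct cells are close to spatially independent, and
this choice recovered planted sources most reliably), 30 retained PCs
for real-sized data (tests and the bundled runner use 8 on the small
synthetic movies, where 5 sources plus noise are present), seeded
orthonormal initialization, tolerance 1e-6 on the unmixing rotation,
500 iterations. Non-convergence — typical when pure-noise components
have no skewness to lock onto — returns the best iterate flagged and
warned, which is harmless downstream because such components fail the
classification threshold anyway. Components are ordered by decreasing
temporal skewness.

ROIs are per-component connected regions above mean + 2 SD of the map
with at least 10 pixels (thresholds configurable; the defaults keep
pure-noise maps empty in ≥95% of seeds). Pixels claimed by an earlier
component are not reassigned, keeping labels disjoint. ROI traces are
the spatial mean per frame, z-scored over the recording; zero-variance
traces come back as zeros with a warning.

## Template classification and integration

Five unit-amplitude templates are built from each fish's own schedule:
square waves covering blue or red epochs, and sawtooths (instant rise,
exponential decay, τ = 10 s default — the waveform kind is standard,
the decay form and constant are our choice and exposed as
configuration) at all onsets, all offsets, or blue offsets only. The
"mixed" templates include both colors' edges. A component is assigned
the arg-max-correlation category iff that correlation exceeds 0.5;
exact ties break by fixed key order. The sustained blue response is
captured by the square blue-onset template.

Same-category maps from different fish are registered by the integer
translation maximizing 2-D cross-correlation with the reference fish's
map — translation only, no rotation or scale — and averaged per pixel
over the animals present there (unweighted; correlation-weighted
averaging was considered and rejected as an unforced deviation from the
plain-average convention). Offsets are reported per fish.

## Problem sizes

The test suite and the bundled runners use deliberately small synthetic
problems — 36 × 28 to 40 × 30 px fields of view, 4 light pulses
(8 minutes at 7.1 Hz), 8 retained PCs, 7 fish, 20-seed repetitions for
classification and 100–200 seeds for power/type-I calibration — sizes at
which every planted effect is still comfortably detectable and the full
battery runs in a couple of minutes. All generators are reproducible
bit-for-bit from their seeds.

## Known limitations

* The behavior model has no per-fish latent responsiveness, adaptation,
  or light-history dependence; occurrence counts calibrate the marginal
  rate only.
* Jennrich sample sizes taken as raw time-sample counts overstate the
  effective n of autocorrelated traces; between-group *comparisons* are
  still meaningful because both groups are treated identically.
* The imaging arm does not model motion, bleaching or overlapping
  footprints with identical responses (the latter are detected and
  warned as unidentifiable).
* Registration assumes the same field-of-view size across fish and pure
  translation misalignment.
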