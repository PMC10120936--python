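# Methods

This note documents the models, numerical choices and known limitations of
the `vocalfold` pipeline: what each stage assumes, which parameters matter,
what the synthetic generators do and do not emulate, and therefore what a
green test suite does and does not establish about real data.

## Acoustic event extraction

Raw audio is 16-bit PCM at 44.1 kHz; stereo input is mixed down (default:
per-frame channel mean; left/right selectable). Candidate events are
maximal runs where a moving-average volume trace crosses a threshold of
500 on the raw PCM amplitude scale. Choices:

- **Volume definition.** Mean absolute amplitude over a centered window
  (truncated at the edges), with an RMS variant behind a switch — the
  original extraction's exact statistic is not documented, and both are
  dimensionally consistent with a threshold of 500 on a 16-bit scale.
- **Window length 100 ms** (configurable): shorter than the 0.5 s minimum
  squeal so onsets are not smeared away, long enough to bridge individual
  pitch periods.
- **Gap merging 200 ms**: runs separated by less than this are one event,
  so amplitude dips inside a call do not split it.
- **Squeal rule**: duration ≥ 0.5 s, boundary inclusive. Sample indices
  are 0-based half-open. Refinement of onsets/offsets to perceptual
  landmarks is a labeling task, not automated here: segmentation supplies
  candidates; label files are the analysis input.

Recovery phases on the signed days-from-surgery axis: PRE [−33, −1],
POST_EARLY [0, 14], POST_MID [50, 100], POST_LATE [150, ∞); days in gaps
belong to no phase and are excluded from comparisons.

## Feature definitions and numerics

All six parameters are computed per event from the event samples only,
with one shared configuration.

- Whole-event spectra are Hann-windowed and zero-padded to the next power
  of two; Q50 interpolates linearly inside the crossing bin. A relative
  tolerance of 1e−12 in the cumulative comparison keeps exactly-split
  spectra (two equal tones) from resolving into the flat plateau between
  peaks by floating-point noise.
- Flux framing: 1024-sample frames, 50% hop, Hann. Frames are normalized
  (unit total energy for Flux1, unit L2 norm for Flux2) before
  differencing, so flux measures spectral shape change rather than
  loudness drift; normalization is switchable.
- Mel filterbank: 64 triangular bands, HTK Mel formula
  (m = 2595·log10(1 + f/700)), 50 Hz to Nyquist. Spread and P60 use the
  band center frequencies in Hz; Spread is the energy-weighted standard
  deviation about the centroid ("average deviation" is read as the second
  moment; a mean-absolute-deviation variant is available). P60 is
  deliberately discrete — band centers are the spectrum's components — so
  no interpolation between bands.
- LPC: biased autocorrelation estimates, Levinson–Durbin recursion,
  order 16, reported coefficient index 8 (1-based), predictor sign
  convention (positive coefficients multiply past samples). No
  pre-emphasis. Constant or all-zero signals raise rather than return
  noise.
- Display scaling (Flux1 × 10³, Flux2 × 10¹) is applied only by the
  presentation helper; stored values are natural scale.

## Feature screening and redundancy

Screening fits an independent Gaussian to each group (sample mean/SD) and
computes the overlapping coefficient. The equal-variance case uses the
closed form 2Φ(−|Δμ|/2σ); otherwise adaptive quadrature over the joint
μ ± 8σ envelope (error ≪ 1e−8). Overlap is symmetric, invariant to common
affine maps, and decreases with standardized separation — these are tested
properties. A two-component mixture EM is deliberately out of scope: the
screening's operative definition is per-group Gaussians plus overlap.

Redundancy uses the bias-corrected distance correlation (U-centered
estimator; negatives reported, not clipped; needs n ≥ 4). The biased
double-centered variant is available. Note that pooling pre- and
post-surgery squeals inflates every pairwise dependence through the common
surgery effect; redundancy is therefore best read within one state.

## Longitudinal testing

Balanced sampling draws the same number of squeals (default: the minimum
per-date count) uniformly without replacement from every recording date in
a phase, so no session dominates. The one-sided Wilcoxon rank-sum test
uses exact enumeration when the pooled sample is ≤ 16 and tie-free,
otherwise the normal approximation with midrank tie handling and
continuity correction. Bonferroni correction multiplies by the full family
size (2 or 36) even when fewer hypotheses are actually computed — test
directions cannot be fixed for every candidate feature, but the family
stays its full size; this conservatism is intentional, matching the study
design's preference over FDR control.

Per-feature test directions are supplied as a table; defaults encode the
expected post-surgery changes (Q50 ↓, P60 ↓, Flux1 ↑, Flux2 ↑, Spread ↑,
LPC8 ↑ toward zero from negative). For improvement comparisons
(POST_EARLY vs later windows) directions invert automatically.

Calibration is verified at the feature-table level: 1000 null cohorts
(identical pre/post distributions, multi-date structure) through the full
balanced-sampling + test + correction chain give a corrected rejection
rate within α + 3·SE, and power rises monotonically with programmed shift.
Running calibration on feature tables rather than synthesized audio is a
deliberate choice: the audio front end is deterministic per squeal, so the
stochastic behavior under calibration lives entirely in the sampling and
testing machinery.

## Fiber-directionality chain

Filter widths follow the ImageJ radius convention ((2r+1)² neighborhoods):
median radius 2, mean radius 3. Intensity normalization rescales each
image so its 99.5th percentile maps to full scale (the reference statistic
is a declared choice). The saturation stretch (4% of pixels clipped to
full scale, ImageJ semantics) is per-image optional — in the study design
it compensates a dim control image. Otsu thresholding ignores black
(zero-valued) pixels so empty mosaic regions cannot drag the threshold;
particles below 50 µm² (8-connectivity; conversion via pixel size, which
is mandatory metadata) are removed; the binary mask is then mean-filtered
into a graded image for gradient estimation.

**Orientation.** Each pixel's orientation comes from a structure tensor:
Gaussian-derivative gradients (σ = 1 px) pooled by Gaussian smoothing
(ρ = 3 px), dominant direction rotated 90° to the fiber axis, folded into
[0°, 180°), with pixels below 10% of the maximum tensor energy marked
undefined. Neighborhood pooling is essential: a bare 3×3 gradient on
near-binary input quantizes angles to rational-slope artifacts (0°, 26.6°,
45°…), producing comb-like histograms that defeat any curve fit. The
tensor realizes "orientation from neighboring structures" and measures a
stripe pattern's angle to within ~1° at any orientation (tested, including
rotation equivariance).

**Histogram and fit.** Orientations of masked, defined pixels are tallied
into 2° bins. The fitted "normal curve" is a wrapped normal (the bump plus
its ±180° images) with a constant baseline: the wrap images keep broad
distributions honest (a plain truncated Gaussian recovers a programmed 40°
width as ≈37° even on ideal data), and the baseline absorbs the isotropic
floor contributed by fiber crossings and end caps. Two passes: fit to
locate the peak (alignment), rotate bins so the peak sits at 0°, re-fit;
dispersion is the second fit's σ in degrees and GoF its R² clamped to
[0, 1]. Near-uniform histograms yield large dispersion and GoF near 0
rather than errors. Alignment difference is the circular distance
min(|Δ|, 180 − |Δ|) ∈ [0°, 90°].

## Synthetic generators

**Squeals** are harmonic stacks, not a biomechanical phonation model; the
acceptance surface is the feature pipeline's behavior, not voice realism.
Controls and defaults: f0 drawn per squeal from 900–1500 Hz with ±4% slow
drift; 24 harmonics with amplitudes following a spectral tilt
(dB/octave) — the pre-surgery profile uses −2 dB/oct (bright), the early
post-surgery profile −16 dB/oct (emulating the dramatic loss of
high-frequency energy); per-frame (≈23 ms) multiplicative jitter on both
harmonic amplitudes and f0 (coefficient 0.25 × instability), with
instability 0.05 pre vs 0.45 post — pitch roughness is the dominant flux
contribution of a hoarse voice, and amplitude jitter alone is nearly
invisible to normalized flux when energy concentrates in one harmonic;
sharp 15 ms onset, exponential decay to an inflection at 60% of the
duration, then linear decline; white noise floor at −45 dB re peak. LPC8's
post-surgery shift toward zero emerges from the spectral-envelope
flattening rather than explicit formant control — an acknowledged
approximation. Effect sizes are generator design choices made to
reproduce the study's direction/significance pattern, not its printed
magnitudes, which depend on unavailable raw audio.

**Cohorts** place squeals in silence-separated recordings per recording
day, with per-date random offsets of tilt, instability and f0 range
(between-date variability 0.15) emulating the strong session-to-session
variation of spontaneous phonation, and an optional recovery model
(linear or logistic in days) interpolating post-surgery parameters back
toward the pre-surgery profile.

**Fiber phantoms** render Gaussian-profile line segments (default: 500
fibers of 25–70 µm on a 768² grid at 0.5 µm/px, width 1.5 µm) with axial
orientations drawn from a wrapped normal whose circular SD equals the
requested von Mises concentration's equivalent (the κ parameterization and
the exact SD↔κ conversion via Bessel functions are provided); the elastin
channel's mean orientation is offset by a programmed angle. Half-normal
background noise and optional single-pixel specks (for particle-filter
tests) are added. The wrapped normal is used because it is the axial
distribution the normal-curve readout is calibrated for; an actual von
Mises shape at 40° SD is intrinsically recovered ≈26% narrow by any
normal-curve fit.

All generators are pure functions of spec + seed (NumPy `SeedSequence`
hierarchical spawning; master fixture seed 20230421).

## Problem sizes

Defaults were sized so the full suite runs in about a minute and the
acceptance script in under a minute on one core: cohorts of 2 pigs × 6
sessions × 8–12 squeals (plus a 12-session recovery pig), a 20-phantom
recovery grid, 1000 calibration replicates at the feature-table level.
These are the package's chosen study conditions for its own verification,
far smaller than the original corpus (thousands of squeals); the testing
machinery itself is size-agnostic.

## Limitations

- Squeal synthesis omits subharmonics, deterministic chaos and vocal-tract
  resonances of real pig phonation; passing tests show the pipeline
  recovers programmed contrasts, not that the parameters are optimal
  biomarkers for real squeals.
- Phantoms are straight fibers with stationary statistics; real lamina
  propria has curvature, bundling, density gradients and channel bleed.
  Dispersion recovery degrades toward broad distributions (σ = 40°), where
  sampling noise of the fiber draw itself dominates.
- The exact flux algorithms of the source feature sets are proprietary or
  external; the formulations here (normalized L1 frame difference; RMS
  unit-norm Euclidean distance) are declared, configurable
  interpretations.
- Screening defaults operate per animal (each subject its own control);
  pooled screening is a flag. No cross-animal mixed-effects modeling is
  offered, by design.
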