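# vocalfold

Quantitative assessment of vocal-fold recovery after laryngeal implant
surgery in pigs, from two independent data streams:

1. **Acoustics** — spontaneous high-pitched vocalizations ("squeals",
   thought to originate at the vocal folds) are segmented from long home-pen
   recordings, reduced to six voice parameters, and compared across
   recovery phases with a balanced-sampling nonparametric testing scheme.
2. **Fiber microscopy** — collagen (second-harmonic generation) and elastin
   (autofluorescence) channels of lamina-propria mosaics are reduced to
   orientation histograms whose normal-curve fits quantify fiber alignment,
   dispersion, and collagen–elastin co-alignment.

The package is aimed at researchers analyzing animal voice recovery or
fibrous-tissue organization who need the full pipeline — segmentation,
features, screening, statistics, image chain — as tested, scriptable
Python. Because the original recordings and slides are not redistributable,
the package ships ground-truthed synthetic generators (harmonic-stack
squeals, rendered fiber phantoms) that emulate the study conditions and
make every stage verifiable end to end.

## The measures

For a squeal with one-sided energy spectrum $E(f)$:

- **Q50** — the frequency splitting the spectrum into equal-energy halves:
  the smallest $f^\*$ with $\sum_{f \le f^\*} E(f) \ge \tfrac12 \sum_f E(f)$.
  Sensitive to the post-surgical loss of high-frequency energy.
- **Flux1** — mean over neighboring analysis windows (1024 samples, 50%
  hop, Hann) of the mean absolute difference between unit-energy frame
  spectra; rises with phonation instability.
- **Flux2** — an alternative flux formulation: RMS Euclidean distance
  between consecutive unit-norm magnitude spectra.
- **Spread** — energy-weighted standard deviation of Mel-band center
  frequencies about the spectral centroid (64 triangular HTK-Mel bands,
  50 Hz–Nyquist).
- **P60** — the Mel component at which cumulative band energy reaches 60%.
- **LPC8** — the 8th of 16 linear-prediction coefficients
  (autocorrelation method, Levinson–Durbin recursion, predictor convention
  $\hat x[n] = \sum_k a_k x[n-k]$); tracks vocal-tract filter changes.

Feature screening models each parameter's pre- and post-surgery
distributions as Gaussians and ranks parameters by the overlapping
coefficient $\mathrm{OVL} = \int \min(f_{\text{pre}}, f_{\text{post}})$;
redundancy among retained parameters is measured with the bias-corrected
(U-centered) distance correlation of Székely and Rizzo.

Longitudinal testing draws equal numbers of squeals from every recording
date inside a phase window (PRE = days −33…−1, POST_EARLY = 0…14,
POST_MID = 50…100, POST_LATE = 150+), applies one-sided Wilcoxon rank-sum
tests in the direction of expected worsening (pre vs early post) or
improvement (early post vs later, directions inverted), and controls the
family-wise error with Bonferroni (2 tests for evaluation A, 36 for
evaluation B).

The image chain per channel: median filter (2 px radius) → cross-image
intensity normalization → optional 4% saturation stretch → Otsu threshold
ignoring black background → removal of particles < 50 µm² → mean filter
(3 px radius) → per-pixel local gradient orientation (structure-tensor
pooled) → directionality histogram over [0°, 180°) → two-pass wrapped
normal + baseline fit giving alignment (peak position), dispersion (fitted
σ in degrees) and GoF (R² ∈ [0, 1]); the collagen–elastin **alignment
difference** is the circular distance between channel alignments.

## Worked example

Generate a one-pig synthetic cohort (3 pre-surgery and 3 early
post-surgery recording sessions, 12 squeals each), compute the feature
table and run evaluation A:

```python
from vocalfold.synthetic import CohortSpec, generate_cohort
from vocalfold.features import compute_feature_table
from vocalfold.stats import run_comparisons, SamplingPlan

spec = CohortSpec(pig_ids=("pig_a",), recording_days=(-30, -20, -10, 3, 8, 13),
                  squeals_per_day=12, seed=11)
recordings, labels = generate_cohort(spec)
table = compute_feature_table(recordings, labels)
print(table.groupby("phase")[["q50", "flux1", "flux2", "spread", "p60", "lpc8"]]
      .mean().round(4))
res = run_comparisons(table, ["q50", "flux1"], [("PRE", "POST_EARLY")],
                      family_size=2, plan=SamplingPlan(seed=1))
print(res[["feature", "direction", "n_a", "n_b", "p_corrected", "significant"]]
      .to_string(index=False))
```

```
                  q50   flux1   flux2     spread        p60    lpc8
phase
POST_EARLY  1189.4625  0.0023  0.8219   454.7403  1218.4227  0.0041
PRE         6477.5432  0.0017  0.6671  5913.6532  8747.2676 -0.1610
feature direction  n_a  n_b  p_corrected  significant
    q50 a_greater   36   36 3.046341e-13         True
  flux1    a_less   36   36 6.678742e-12         True
```

Q50 collapses from ≈6.5 kHz to ≈1.2 kHz after the programmed high-frequency
loss while Flux1 rises with the programmed instability; both survive the
family-of-two Bonferroni correction on the balanced sample (36 squeals per
phase, 12 per date). Fiber side:

```python
from vocalfold.synthetic import (FiberPhantomSpec, generate_fiber_phantom,
                                 kappa_from_angular_sd)
from vocalfold.fiberdir import analyze_sample

spec = FiberPhantomSpec(kappa=kappa_from_angular_sd(20.0),
                        channel_offset_deg=5.0, seed=3)
collagen, elastin, truth = generate_fiber_phantom(spec)
res = analyze_sample(collagen, elastin, spec.pixel_size_um)
```

yields (programmed truth: angular SD 20°, channel offset 5°):

```
alignment_difference_deg        4.936
alignment_collagen_deg         40.390
alignment_elastin_deg          45.325
gof_collagen                    0.979
gof_elastin                     0.971
dispersion_collagen            18.972
dispersion_elastin             18.138
```

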