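# Methods

## Overview

`circatemp` analyses minute-resolution wrist skin-temperature recordings
from free-living wearers of thermochron-style loggers. The pipeline runs
simulate → preprocess → cosinor fit → cluster → sleep summary → association
inference; every stage is seeded and writes its artifacts. This note
documents the models, the tunable parameters and their defaults, the
numerical choices, what the synthetic generator does and does not emulate,
and the known limitations.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated.

Each subject belongs to one of three archetypes whose parameters are
shipped as a versioned YAML fixture (`data/archetypes.yaml`):

| archetype | mesor (°C) | amplitude (°C) | period (h) | peak | DSP prob | onset | n |
|---|---|---|---|---|---|---|---|
| cluster1 | 34.29 | 1.02 | 25.75 | 02:40 | 0.46 | 00:12 | 100 |
| cluster2 | 33.46 | 1.38 | 25.76 | 02:34 | 0.68 | 02:03 | 130 |
| cluster3 | 32.80 | 2.09 | 25.33 | 02:02 | 0.37 | 00:48 | 51 |

A subject's recording is 72 h at one sample per minute, started uniformly
between 15:00 and 22:00 (devices are handed out in the afternoon/evening).
Realized cosinor parameters are jittered around the archetype values —
mesor and amplitude SD 0.15 °C (amplitude truncated above 0.2 °C so the
rhythm stays detectable), period SD 0.4 h. The measurement layers are:

- **AR(1) sensor noise.** Skin temperature residuals are strongly
  autocorrelated, so noise is AR(1) with coefficient 0.9 and innovation SD
  `sigma` (default 0.4 °C; the stationary SD is `sigma/sqrt(1-0.81)`).
  `NoiseSpec.from_marginal_sd` constructs a spec from the marginal SD when
  a study specifies noise on that scale.
- **Warm-up transient.** The logger starts below skin temperature; the
  first 120 min carry an additive ramp of default depth 2 °C. This is the
  feature that motivates re-anchoring records to noon.
- **Quantization** at 0.0625 °C, the sensor resolution of the emulated
  DS1922L-class device.
- **Missing runs.** Re-attachment gaps are contiguous runs of 5–90 min
  covering ~5 % of samples by default (never ≥ 50 %).

Sleep behaviour: 8 nights per subject; onset ~ Normal(archetype onset,
archetype SD), duration ~ N(8 h, 40 min), sleep-onset latency
~ N(20, 8) min (truncated ≥ 0), WASO ~ N(55, 15) min (truncated ≥ 0). The
DSP label is Bernoulli(archetype probability); labelled subjects are
guaranteed ≥ 4 of 8 onsets after 01:00 and unlabelled ones ≤ 2, so the
rule-based classifier recovers labels exactly — by construction, not as an
empirical finding. MEQ item responses (six items, ranges 1–4 except one
1–5) are sampled so the sum is ~ N(archetype mean, SD 4), clipped to the
legal range; the SD is chosen so bootstrap CI widths on cluster means are
realistic for cohorts of this size, since only cluster means are fixed by
the fixture. Demographics default to age ~ N(16.9, 0.12), BMI ~ N(21.7, 3),
30 % male.

**What the generator does not emulate:** movement and posture artefacts,
light exposure, ultradian and menstrual components, device drift, and any
dependence of temperature on the sleep episodes themselves (temperature and
sleep are linked only through cluster membership). Passing recovery tests
therefore shows the estimators are correct and calibrated under a
plausible noise model — not that the pipeline is robust to every artefact
of real recordings.

## Preprocessing

- **Noon harmonization.** Every record is cut to the 48 h (2880 samples)
  starting at the first noon at or after the recording start. "12 p.m." is
  read as noon — consistent with the purpose of dropping the evening
  attachment transient. A start at exactly noon keeps its first sample; a
  record too short to fill the window is flagged unusable rather than
  silently truncated. A 3-day recording started 15:00–22:00 always
  contains the window, so all subjects get equal-length vectors without
  padding.
- **Imputation.** Missing cells are completed on the subjects × timepoints
  matrix (cross-subject borrowing) by regularized iterative PCA: initialize
  at column means, then iterate column-center → rank-`ncp` SVD with
  singular values shrunk by the mean trailing eigenvalue → refill missing
  cells, until the largest change is below 1e-6 (cap 1000 iterations, with
  a warning on non-convergence). Observed cells are never altered. Default
  `ncp = 2`; order is harmonize → impute.
- **Loess smoothing.** Degree-2 local regression with tricube weights,
  span 0.3 (fraction of the 2880 points per window). On the uniform minute
  grid the smoother is a fixed linear map, so the interior reduces to one
  equivalent-kernel convolution with exact per-index kernels at the
  boundaries; the kernel matrix is cached per (length, span, degree).
- **Spline sensitivity smoother.** A GCV-penalized cubic smoothing spline.
  The GCV solve runs on every 4th sample (the series are heavily
  oversampled; the fit changes by ~0.04 °C RMS while cutting cost several-
  fold) and is evaluated on the full grid. If GCV degenerates to an
  interpolant (noiseless input), a least-squares regression spline with
  ~30 effective df is used instead, with a warning.
- **Sensitivity exclusion.** A subject is excluded when the loess- and
  spline-based cosinor fits disagree by more than 2 h in period or 25 %
  in relative amplitude. These thresholds are configurable choices — no
  numeric criterion is canonical — and the defaults keep the exclusion
  fraction around or below the ~10 % seen in practice.

## Cosinor fitting

For fixed period the fit is ordinary least squares on
`[1, cos(2πt/τ), sin(2πt/τ)]`; amplitude is `hypot(β, γ)` and the
acrophase angle is resolved over all four quadrants from the signs of
(β, γ) (equivalent to a full-range two-argument arctangent), with
`β = A cos φ`, `γ = −A sin φ` and peak time `(−φτ/2π) mod τ`. The period
is profiled out by a 1-D search — coarse 6-min grid over [20, 30] h, then
golden-section refinement to 1 min — reaching the same optimum as joint
nonlinear fitting without convergence fragility. Degenerate cases: a
constant series has a flat RSS profile and is reported with amplitude 0 and
undefined period; a period far beyond the window makes the regressors
collinear and is rejected via a condition-number guard.

Two timing conventions coexist deliberately: *model* acrophase/bathyphase
are the first peak/trough of the fitted curve after the window start
(trough = peak + τ/2), while *observed* extrema are read directly off the
smoothed data, cycle by cycle (24-h cycles from the window start), and
summarized by a circular mean on a 24-h dial — peaks at 23:30 and 00:30
average to 00:00. Both are reported because they genuinely differ on real
and synthetic data; constant cycles are skipped.

## Clustering

Features are the DC term plus the first H = 24 harmonics (real/imaginary
pairs) of the DFT of the 48-h series, normalized by length so the DC term
equals the series mean. H = 24 keeps periods of 2 h and longer over the
window; it is configurable. The DC term is kept by default because mean
level is a genuine cluster separator; `drop_dc` gives shape-only
clustering, and a magnitudes-only mode exists for phase-invariant
clustering (default is pairs).

PAM is implemented directly: greedy BUILD, then steepest-descent SWAP
applying the best single medoid exchange until none improves, so solutions
are locally optimal under single swaps; 10 restarts over permuted input
orders keep the best cost; everything is deterministic given the seed.
Labels are renumbered so cluster 1 has the highest mean DC term
(highest-mesor-first reporting convention). Validity: Silhouette
(singletons score 0) and Davies–Bouldin via scikit-learn, Dunn
(min between-cluster distance over max diameter, guarded at 1e12 for
zero-diameter clusters) in-package.

The RMSEA-like and eBIC-like indices are a **documented reconstruction**,
not a published formula: for candidate dimension k, a Bartlett-style
statistic tests sphericity of the p−k trailing eigenvalues of the feature
covariance (features reduced to ≤ 10 principal components first), with
`RMSEA = sqrt(max(0, (χ²/df − 1)/(n−1)))` and `eBIC = χ² − df·ln n`. They
are labelled `*_like` throughout and should be read as heuristics. Because
the small-sample factor depends on k, the RMSEA-like sweep is guaranteed
non-increasing only on spectra with well-separated eigenvalues.

`select_k` surfaces one vote per index (max Silhouette, max Dunn, min DB,
first k with RMSEA-like < 0.05, min eBIC-like) plus a majority consensus
with ties broken toward smaller k; disagreement is never collapsed
silently. t-SNE re-clustering agreement (ARI) and Newman modularity on a
Gaussian-kernel 10-NN graph (σ = median pairwise distance,
Fruchterman–Reingold layout with fixed seed) are stability diagnostics,
not the clustering itself.

## Sleep, DSP and MEQ

Clock-time moments are taken on an 18:00-anchored linear scale — the one
place where clock arithmetic could break, safe here because onsets in this
population never cluster near 18:00. Assumed sleep is offset − onset;
SOL is onset − bedtime; midpoint is onset + duration/2; regularity is the
night-to-night SD of onset and midpoint in minutes.

The DSP rule is: onset *strictly* after 01:00 on ≥ 3 nights per week,
normalized by observed nights (`(late/n)·7 ≥ 3`) because measurement
windows vary in length; nights with missing onsets drop out of both
numerator and denominator. Onset (not bedtime) is the default event, since
the rule describes actigraphy-measured sleep; a bedtime mode exists.
The MEQ score is the plain sum of the six short-form items; per-item
response ranges live in a scoring table, not in code, and a missing item
makes the score undefined (no prorating).

## Inference

- **BC bootstrap CIs** (bias-corrected percentile, no acceleration term):
  `z0 = Φ⁻¹(fraction of resample statistics below the point estimate)`
  with ties counted half, endpoints at `Φ(2z0 ± z_{0.975})`; B = 1000.
  Degenerate resample distributions collapse the interval to the point and
  are flagged.
- **Omnibus p-values** resample an F-type statistic under a null imposed
  by within-group centering (group effects removed, residuals pooled,
  grand mean restored); B = 500, `p = (1 + #{F* ≥ F})/(B + 1)`. A
  label-permutation mode is available. Pairwise contrasts resample each
  group's centered residuals.
- **Logistic models** are maximum-likelihood fits; continuous predictors
  are z-scored so ORs are per SD; complete separation is detected (by the
  fitter or by runaway coefficients) and reported as non-estimable.
  Supported model forms: clusters only, cosinor parameters only, and
  clusters + cosinor.
- **FDR.** One Benjamini–Hochberg family covers all omnibus tests of a
  pipeline run; pairwise p-values are corrected within their own family.
  The step-up adjusted p-values are order-preserving and cross-checked
  against a direct step-up implementation.

## Validation studies and problem sizes

`circatemp.studies` packages the recovery experiments used for
acceptance: 200 series per archetype for cosinor recovery (AR(1) noise at
marginal SD 0.4 °C); the full 281-subject cohort for cluster-structure and
DSP-rate recovery; 200 replicate cohorts (n = 281) for logistic OR
recovery; 1000 simulations for BC-bootstrap coverage (n = 50, B = 1000);
and 500 simulations for omnibus-p calibration under permuted labels
(B = 500). These sizes keep each study in the tens of seconds on one CPU
while leaving Monte-Carlo error well below the effect sizes of interest.

## Known limitations

- The cosinor is single-component; multi-component and population-mean
  cosinor variants are out of scope.
- The RMSEA/eBIC dimension indices are heuristic reconstructions (above).
- Imputation borrows across subjects; with very few subjects it degrades
  toward column means. A per-subject interpolation fallback exists.
- The generator's independence of temperature noise and sleep behaviour
  means cross-domain associations in synthetic data arise only through
  cluster membership; real data will show richer coupling.
- Bootstrap p-values are discrete at resolution 1/(B+1); families of very
  small p-values need larger B.
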