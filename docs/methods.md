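# Methods

This note documents the models, conventions, and design choices behind
`rsmvpa`, in the order data flows through the pipeline.

## Scope and assumptions

Inputs are assumed spatially aligned to a common grid: slice-timing
correction, realignment, and normalization to a template are upstream of
this package. Per subject and session the pipeline takes a 4D BOLD run,
a 3D brain/gray-matter mask shared by all subjects, a 6-column motion
file (3 translations in mm, 3 rotations in radians), WM/CSF mean
signals, and a clinical table with CAPS totals at baseline,
post-treatment, and long-term follow-up. Grid or affine mismatches are
hard errors, never resampled away.

## Preprocessing

- **Volume discarding** removes the first `n_discard` (default 5)
  volumes; nuisance traces are truncated in step, so regressor rows
  always match the retained series. Whether WM/CSF traces were extracted
  before or after discarding is irrelevant here because rows are aligned
  by construction.
- **Nuisance regression** fits one joint OLS design per voxel:
  intercept, linear trend, WM, CSF, and the Friston-24 motion expansion
  (the 6 parameters, their one-volume lags zero-padded at the first
  timepoint, and both sets squared). A joint fit is used because joint
  OLS residuals are invariant to regressor ordering, which makes
  "sequential" regression well-defined; a literal stagewise
  residualization is available via `sequential=True` for comparison.
  The design is solved by pseudoinverse, so rank deficiency (e.g., zero
  motion) can never error. The linear trend is included because ALFF is
  undefined under strong drift; it is disablable. Global signal
  regression is deliberately not implemented, even as an option.
- **Ideal filtering** is a rectangular DFT-domain projection with
  inclusive band edges; lowpass retains the DC bin (Pearson correlation
  is mean-invariant, so DC retention cannot affect degree centrality).
  Being a projection it is idempotent, which the tests assert.
- **Smoothing** is separable Gaussian convolution with
  σ = FWHM / (2√(2 ln 2)) / voxel size per axis, zero-padded borders,
  applied to the full volume and re-masked (not mask-renormalized,
  matching conventional volumetric smoothing). FWHM 0 is the identity.
- **Motion screening** (1.5 mm / 1.5°) is a reported flag per run, not
  an automatic exclusion.

## ALFF

The residual series is smoothed (6 mm FWHM) *before* spectral analysis.
Per in-mask voxel the un-tapered, un-padded DFT (transform length =
series length) gives one-sided amplitudes `2|X_k|/t`; ALFF is their mean
over bins with `0.01 ≤ f_k ≤ 0.08` Hz inclusive, `f_k = k/(t·TR)`. At
t = 200, TR = 2 s this is bins k = 4..32 (29 bins). The amplitude
convention is fixed so an on-bin unit sinusoid reads amplitude 1 (hence
ALFF = 1/29 when it is the only band content); any fixed positive
scaling cancels under the global-mean standardization, so the choice is
observable only in raw maps. The DC bin can never enter the band because
the low edge must be positive. ALFF is computed on fully
nuisance-regressed residuals (not detrended-only); the pipeline order is
fixed and tested.

## Degree centrality

Computed on lowpass-filtered (≤ 0.08 Hz), *unsmoothed* residuals —
smoothing first would inflate neighbor correlations, so on this path the
finished map is smoothed last. Each in-mask series is scaled to zero
mean and unit norm, making every pairwise dot product the Pearson r;
degree is the count of other voxels with r strictly greater than the
threshold (default 0.25; ties at the threshold excluded; negative and
sub-threshold correlations contribute nothing). Zero-variance voxels are
defined to have r = 0 with everything — degree 0, never a neighbor —
which avoids NaN propagation and is stable under blocking. The blocked
algorithm computes correlation blocks of at most `block_size` rows
against all voxels and accumulates per-threshold counts in one pass
(the whole sweep reuses each block), bounding memory regardless of mask
size; its counts are identical to the dense all-pairs oracle. Order on
this path: degree → standardize (divide by in-mask mean) → smooth.

## Outcome labels

Remission is `(caps_pre − caps_followup)/caps_pre ≥ 0.5`, boundary
inclusive; the 2-year follow-up score defines the long-term label. The
acute (post-treatment) response under the same rule is provided
separately but unused by the classifier path.

## Classification

Feature rows are a subject's in-mask voxel values in mask scan order
(x fastest). Modalities are combined either by

- **concatenate** (default): divide each modality's features by
  √(mean diagonal of its centered linear kernel), then column-concatenate
  — equivalently, sum trace-normalized linear kernels. Normalization
  puts ALFF amplitudes and DC counts on a common kernel scale; how the
  original toolchain normalized modality kernels is unstated, so trace
  normalization is this package's documented choice. Or
- **stack_samples**: each modality contributes a separate sample per
  subject (same normalization), all of a subject's rows sharing its
  label and cross-validation fold. This scheme exists because class
  denominators of the emulated study's combined condition are consistent
  with modalities entering as separate samples; neither scheme is
  asserted to be the original one.

Cross-validation is leave-one-subject-out: feature means are computed on
training rows only and applied to both sides (leakage-safe; whole-cohort
centering is available behind a flag, off by default). The classifier is
a soft-margin linear SVM with C = 1 (the library default for
high-dimensional, small-n data). A decision value of exactly 0 predicts
the positive (remitted) class; this tie rule is documented and
exercised. Internally each fold is solved in kernel space: per-fold
centering is a rank-one correction of the subjects' Gram matrix, exactly
equivalent to feature-space centering for a linear kernel, and the
per-fold kernels are label-independent, so the permutation test reuses
them across all permutations. The solver is libsvm via scikit-learn's
low-level binding, with the public `SVC` as fallback; a unit test pins
exact agreement between the kernel route and explicit per-fold-centered
`SVC` fits.

The permutation test re-pairs subject labels uniformly at random
(seeded; a seed is mandatory), reruns the full cross-validation per
permutation, and reports `p = (1 + #{null ≥ observed})/(1 + B)` — the
add-one estimator never returns 0. B defaults to 1000. ROC curves sweep
the held-out decision values over all thresholds with remitted positive;
tied values contribute half weight, so the trapezoidal AUC equals the
normalized Mann–Whitney U (asserted against an independent oracle).

## Discrimination map

The final map refits the SVM on all subjects with full-cohort centering
(there is no held-out subject for this fit; this is distinct from CV
centering). The primal weight vector is scattered back to one signed
volume per modality; positive weight is evidence for remission.
Thresholding retains `|w| ≥ fraction·max|w|` (inclusive), fraction 0.30
by default, with the maximum taken within each modality's volume — a
fraction *of the maximum*, not a voxel-count quantile. Clusters are
maximal same-sign connected components under 26-connectivity with a
20-voxel minimum (configurable; the floor matches the smallest cluster
the emulated study reports). Reported weights are raw primal weights and
are solver-scale dependent; only ratios are meaningful, and the
fraction-of-max report is scale-invariant by construction. Because the
classifier is multivariate, no local inference should be drawn from
individual weights.

## Synthetic cohort

The generator emulates the study conditions: 20 subjects (9 remitted /
11 persistent; assignment deterministic by subject index, optionally
randomized), TR 2 s, 205 acquired volumes, 18³ grid at 5 mm isotropic
with an ellipsoidal mask (~2,200 in-mask voxels — small enough for dense
DC oracles, large enough for smoothing and clusters to be meaningful).

Each voxel series is `loadings · latents + AR(1) noise`: latents are
unit-SD band-limited (0.01–0.08 Hz) Gaussian processes; noise has lag-1
coefficient 0.3 and marginal SD `noise_sd` (default 1.0). This is the
minimal process exhibiting both temporal autocorrelation (so filtering
matters) and controllable shared variance (so degree effects are
injectable). Baseline voxels load (0.6) on a single latent chosen by
spatial slab along x, giving the connectivity graph non-trivial
structure. ALFF effect regions multiply the latent component by a
group-specific factor (default 2.0 vs 1.0); hub effect regions replace
the loading row with a group-specific loading on *all* latents (default
1.2 vs 0.2), raising correlation with every slab and hence degree.
Setting multipliers to 1 and equal hub loadings yields an exchangeable
null cohort (`SyntheticConfig.null`). Baseline CAPS follows a truncated
normal on [45, 136] whose *truncated* mean and SD are 67.3 and 14.5
(parent parameters solved numerically — truncating a normal at the
instrument floor would otherwise shift the mean up by ~2 points);
follow-up improvement is drawn ≥ 0.5 for designated remitted subjects
and < 0.5 otherwise, so labeling recovers the truth exactly. Motion is a
small-amplitude random walk; WM/CSF traces are AR(1). Sessions:
`pre` by default; a `post` session re-samples noise under
session-specific sub-seeds and attenuates injected contrasts toward the
group midpoint (`post_attenuation`), mimicking effects washed out by
treatment. Everything derives from one integer seed.

What the generator does *not* emulate: scanner artifacts, slice-timing
or motion-induced signal changes, physiological noise spectra,
spatial autocorrelation of the noise, or realistic anatomy. Passing
tests therefore demonstrate algorithmic correctness and statistical
calibration of the pipeline, not expected performance on real scans —
with ~113-voxel regions and a 2× amplitude effect the synthetic groups
are far more separable than real cohorts (cross-validated accuracy
reaches ceiling, against 65–72.5 % reported for comparable real data).

## Numerical choices and degenerate inputs

- Band-edge comparisons use a 1e-9 relative tolerance so exact bin
  frequencies (k/(t·TR)) at a printed edge are included.
- Rank-deficient nuisance designs: pseudoinverse, never an error.
- Zero-variance voxels: ALFF 0 (no off-DC power), DC degree 0.
- Standardization requires a positive in-mask mean and is idempotent to
  1e-10 (the second pass divides by a mean within rounding of 1).
- Permutation accuracies are compared with `>=` on identically computed
  floats (both are counts divided by the same n).
- All stochastic paths take explicit integer seeds; per-run generators
  derive from `SeedSequence(seed, spawn_key=(subject, session))`, so
  adding a session never changes existing sessions' data.

## Problem sizes in the test suite

Unit tests run on reduced grids (12³, ≤ 65 volumes, ≤ 8 subjects). The
calibration and recovery properties use the full default conditions —
200 null cohorts and 20 effect cohorts of 20 subjects each at 18³, with
B = 200 permutations per cohort (the per-cohort permutation budget for
these replicate studies; single-cohort analyses default to B = 1000).
These sizes were chosen so the whole suite completes on a single CPU in
well under half an hour while keeping the binomial bounds on the
calibration check informative.

## Known limitations

- The CAPS trajectory model is distributional only; item-level scoring,
  comorbidity covariates, and dropout are not modeled.
- Weight-map magnitudes are solver-scale dependent (see above).
- `stack_samples` weight maps live in the shared voxel space and are
  tagged as such rather than split per modality.
- The cluster table annotates anatomy only through a user-supplied
  integer label volume; no atlas ships with the package.
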