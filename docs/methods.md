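# Methods

## Signal model

Each voxel's cleaned BOLD series is modeled as a realization of a
stationary scale-free process with Hurst exponent H ∈ (0, 1); the power
spectrum follows S(f) ∝ 1/|f|^β with β = 2H − 1. The synthetic generator
makes this literal: voxel series are unit-variance fractional Gaussian
noise (fGn) with autocovariance

    γ(k) = ½ (|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}),

plus additive white measurement noise of standard deviation `noise_sd`.
Sampling uses circulant embedding of the covariance (exact in law,
O(n log n)); if the embedding produces negative eigenvalues the generator
falls back to the exact sequential (Levinson–Durbin innovations) sampler
and emits a warning. Exactness matters because the generator doubles as the
ground-truth oracle for the estimator: generator correctness is itself
tested against the closed-form autocovariance and against the identity
Var(Σ_{i≤n} x_i) = n^{2H}.

## Temporal cleaning

Cleaning is applied independently per voxel, in a fixed order: linear
detrend (removes mean and slope), OLS regression on nuisance series (six
motion parameters, white-matter and ventricle signals when provided; an
intercept is always included so residuals are centered), then a zero-phase
ideal band-pass implemented as an FFT boxcar with inclusive band edges,
default 0.01–0.10 Hz. All three operations are linear and length-preserving;
the filter family and edge convention are a deliberate choice — an ideal
filter gives an exactly testable unit-gain passband, and no particular
filter order is canonical in resting-state pipelines. Global-signal
regression is intentionally not offered. The upper cutoff must lie strictly
below Nyquist = 1/(2·TR).

## Rescaled-range estimation

For window length n the series (length N) is cut into ⌊N/n⌋ non-overlapping
segments, the remainder discarded. Per segment, Z_t = Σ_{i≤t}(x_i − x̄) gives
the range R = max Z − min Z, and S is the segment standard deviation in the
**population** convention (divide by n). Segments with S = 0 are skipped;
a scale with no valid segment is dropped; a series with no valid scale at
all (a constant voxel) is flagged undefined, never zeroed. The default
scale grid is 10 integer window lengths log-spaced from 10 to ⌊N/2⌋
(deduplicated): for the default N = 229 this spans 10–114 samples, i.e.
fluctuations of 20–228 s at TR = 2 s. Ĥ is the OLS slope of log₂ mean(R/S)
on log₂ n (base-2 logs fix the reported intercept; the slope is
base-invariant), with the fit's R² and scale count kept per voxel as QC.

**Small-sample correction.** E[R/S] of white noise grows like c·√n only
asymptotically; at finite n the raw slope is biased upward. The corrected
estimator subtracts the Anis–Lloyd closed form

    E[R/S]_n = Γ((n−1)/2) / (√π Γ(n/2)) · Σ_{i=1}^{n−1} √((n−i)/i)

in log space and re-centers the slope at 0.5. Note the (n−½)/n prefactor
sometimes attached to this formula is **omitted**: Monte-Carlo evaluation
shows the bare formula matches the population-SD convention used here to
better than 0.2 % from n = 8 upward, while the prefactor (which approximates
the sample-SD convention, √((n−1)/n)) introduces a 3–7 % mismatch at small n.
The correction is OFF by default and enabled explicitly where unbiasedness
matters.

**Bias behavior** (N = 1024, 50 simulated series per point, default grid):

| true H | raw Ĥ | corrected Ĥ |
|--------|-------|-------------|
| 0.3 | ≈ 0.40 | ≈ 0.34 |
| 0.5 | ≈ 0.55 | ≈ 0.50 |
| 0.7 | ≈ 0.71 | ≈ 0.65 |
| 0.9 | ≈ 0.84 | ≈ 0.78 |

Both variants are strictly monotone in the true H. The corrected estimator
is essentially exact at H = 0.5 (the anchor the correction is built from)
but retains a downward bias under strong persistence: the slow transient of
R/S under long memory is not a white-noise finite-sample effect, so no
white-noise-anchored correction can remove it. Users comparing groups are
unaffected (the map H → Ĥ is monotone), but absolute Ĥ values above ~0.8
should be read as compressed. This residual bias is a documented limitation,
not a tuning target.

## ROI features

Voxel membership is by exact atlas-label equality (no partial-volume
weighting); the feature for region k is the arithmetic mean of defined Ĥ
values over voxels labeled k. An entirely-undefined region is an error
naming the label, so silent gaps cannot propagate. Row order of the feature
matrix follows the participants table verbatim.

## Feature selection

Per training fold, a feature is retained iff its two-sample pooled-variance
Student t-test (df = n₁ + n₂ − 2, two-tailed) gives p < α with α = 0.05,
uncorrected for multiple comparisons — the filter is deliberately
uncorrected, mirroring standard mass-univariate practice for this design.
Retained features are ordered by descending Fisher score

    FS = [n₁(m₁ − m)² + n₂(m₂ − m)²] / [n₁ σ₁² + n₂ σ₂²]

(population variances, matching the n_k weighting); the score documents and
ranks the retained set rather than acting as a second threshold — with both
criteria stated as "used" but only the t-threshold quantified, this is the
reading that reproduces per-fold retention counts of the observed order
under moderate effects. If nothing passes, the fold proceeds with the single
best-scoring feature and a machine-parsable warning (a fold must emit a
prediction). Degenerate features (both groups constant) score 0 when the
group means agree and +∞ otherwise.

## Classification

LOOCV with the selection re-run on every fold's N−1 training rows; the
held-out subject contributes nothing to selection, standardization or
training (asserted by a poisoning test). Retained features are z-scored
with training-fold statistics; the same transform is applied to the test
row — RBF SVMs on raw-scale features would make the fixed γ grid range
meaningless. The kernel is the standard decaying RBF K(x, x′) =
exp(−γ‖x − x′‖²). The grid is γ, C ∈ {2^e : e = −8, −7.5, …, 8} (33 × 33);
ties on accuracy break toward the smallest C, then the smallest γ, so the
result is independent of grid enumeration order.

The headline number is the *maximum* LOOCV accuracy over the grid. This is
an optimistically biased model-selection rule; the bias is surfaced rather
than corrected: the full 33 × 33 accuracy table is persisted, and on null
cohorts the per-point *median* accuracy stays inside the binomial chance
interval while the maximum sits above it. Sensitivity counts correct
patients (MCI = positive class), specificity correct controls; the ROC pools
the per-fold SVM decision values at the best grid point and its AUC equals
the Mann–Whitney concordance probability with ties counted ½ (asserted
against a brute-force pair count). Feature-retention counts over folds are
reported with a stability threshold of ⌈0.95 · n_folds⌉.

A holdout variant splits the cohort once (seeded, stratified, e.g.
42 + 40 train / 22 + 20 test), picks (γ, C) by mean accuracy of an internal
stratified two-fold cross-prediction inside the training subset (selection
re-run per inner fold), then trains on the full training subset and scores
the untouched test subset. A linear-kernel mode is available for
comparison; with it the γ axis collapses to a single value.

## Synthetic cohort defaults

The generator emulates a cohort after spatial preprocessing: 229 volumes at
TR = 2 s (239 acquired minus 10 equilibration volumes), a block-partition
atlas with 246 regions by default (near-cubic cuboid blocks — ROI averaging
needs label identity, not anatomy), baseline H = 0.7 (persistent, typical
of gray-matter BOLD), measurement noise SD 0.3 relative to unit-variance
signal, and a group effect ΔH = −0.15 applied to the affected regions of
patient subjects only. No effect size is published for this contrast, so the
default is a moderate shift chosen once: large enough that a 60-subject
cohort separates reliably after ROI averaging, small enough that single
voxels do not. The shift's sign is configurable; the pipeline is
direction-agnostic. Each subject draws from an independently spawned child
seed, so cohorts are bit-reproducible.

What the generator does *not* emulate: hemodynamic response shape, motion
and scanner artifacts, spatial autocorrelation and anatomy, inter-subject
variance in baseline H. Passing end-to-end tests therefore demonstrates the
statistical machinery (estimation, selection, nested CV, no leakage) under
the assumed signal model — not robustness to the full physiology of real
acquisitions.

## Validation problem sizes

Reference checks run at sizes chosen for tight Monte-Carlo error at
interactive cost: estimator recovery uses 50 series of length 1024 per H;
the white-noise anchor 100 series; the end-to-end classification runs use
30 + 30 subjects, 60 regions × 27 voxels, N = 229, noise SD 0.1, with 15
affected regions at ΔH = −0.15 (and ΔH = 0 for the null control), over the
full 33 × 33 grid.

## Numerical conventions

- Fit logs are base 2; scales are integers; duplicate scales are collapsed.
- Population SD everywhere a variance enters a ratio (R/S segments, Fisher
  score); the t-test uses the usual df = n − 2 pooled sample variance.
- Undefined values are NaN + an explicit mask, never 0.
- All randomness flows from explicit integer seeds via `numpy.random`
  Generators; per-subject streams are spawned from a root SeedSequence.
- Grid tie-breaks, fold order, and feature ordering are all deterministic;
  re-running a pipeline with the same seed reproduces identical output
  checksums (asserted in tests).
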