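# hurstfmri

Voxelwise Hurst-exponent features and SVM classification for resting-state
fMRI group studies.

Resting-state BOLD signals show scale-free temporal structure: their power
spectrum follows S(f) ∝ 1/|f|^β, and the Hurst exponent H ∈ (0, 1) — related
to the spectral exponent by β = 2H − 1 — summarizes that structure per voxel.
H = 0.5 corresponds to uncorrelated noise, H > 0.5 to persistent (positively
correlated) fluctuations, H < 0.5 to anti-persistent ones. Altered temporal
persistence is a candidate imaging marker in early cognitive decline, and a
common analysis asks whether region-averaged H values separate patients with
mild cognitive impairment (MCI) from healthy controls (HC).

`hurstfmri` implements that analysis end to end, for methodologists who want
a tested, reproducible reference implementation:

1. **Temporal cleaning** — per-voxel linear detrend, nuisance regression
   (motion, white-matter and ventricle signals, with intercept), and a
   zero-phase FFT band-pass (0.01–0.10 Hz by default).
2. **Rescaled-range (R/S) Hurst estimation** — for window length n, the
   series is split into ⌊N/n⌋ non-overlapping segments; each segment's range
   R of mean-adjusted cumulative sums is divided by its standard deviation S,
   and Ĥ is the OLS slope of log mean(R/S) against log n over ~10 log-spaced
   windows. An optional small-sample correction subtracts the closed-form
   Anis–Lloyd white-noise expectation E[R/S]_n and re-centers the slope at
   0.5.
3. **Atlas features** — the mean Ĥ of each region of a user-supplied integer
   parcellation (e.g. the 246-region brainnetome scheme) forms a
   subjects × ROIs feature matrix.
4. **Nested classification** — leave-one-out cross-validation of a
   soft-margin RBF SVM over the 33 × 33 grid γ, C = 2⁻⁸, 2⁻⁷·⁵, …, 2⁸, where
   every fold re-runs feature selection (two-sample pooled-variance t-test,
   p < 0.05 uncorrected, ranked by Fisher score
   FS = [n₁(m₁−m)² + n₂(m₂−m)²] / [n₁σ₁² + n₂σ₂²]) on its training rows
   only. Reported: best-grid accuracy, sensitivity/specificity (MCI
   positive), ROC/AUC over pooled decision values, per-feature retention
   counts with a 95 %-of-folds stability threshold, plus a train/test
   holdout variant with internal two-fold model selection.
5. **Synthetic cohorts** — exact fractional Gaussian noise (circulant
   embedding, with a sequential fallback) with ROI-specific Hurst exponents
   gives ground-truth-known inputs for validating the whole chain.

## Worked example

Run the full pipeline on a simulated cohort (10 MCI / 10 HC, 12 regions of
8 voxels, regions 1–3 shifted by ΔH = −0.15 in the MCI group):

```python
from hurstfmri.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    simulate=dict(n_mci=10, n_hc=10, n_rois=12, voxels_per_roi=8,
                  affected_rois=frozenset(range(1, 4)), delta_H=-0.15,
                  noise_sd=0.1),
    out_dir="demo-run", seed=7)
run_dir = run_pipeline(cfg)
print((run_dir / "cv_result.json").read_text())
```

which prints

```json
{
 "accuracy": 0.95,
 "sensitivity": 0.9,
 "specificity": 1.0,
 "auc": 0.9800000000000001,
 "best_gamma": 0.08838834764831845,
 "best_C": 0.25,
 "stability_threshold": 19,
 "stable_features": [1, 2, 3]
}
```

Reading: the best (γ, C) on the grid classified 19/20 left-out subjects
correctly (9/10 patients, 10/10 controls); the AUC of the pooled decision
values is 0.98; and exactly the three truly shifted regions were retained in
at least 19 of the 20 folds — the selection recovered the planted effect.
The run directory also holds the per-point accuracy table
(`grid_accuracy.csv`; note the grid *maximum* is an optimistic summary, the
table lets you report unbiased alternatives), the ROC points, a per-fold
audit log, and a manifest with config, seed and output checksums.

The same stages are exposed on the command line (`hurstfmri simulate`,
`clean`, `hurst`, `features`, `classify`, `run`) for NIfTI/TSV inputs.

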