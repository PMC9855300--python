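# ovradiomics

CT-radiomics histologic subtyping of epithelial ovarian carcinoma (EOC),
built as a tested, reusable pipeline and exercised entirely on synthetic
phantoms and simulated feature tables.

## The problem

EOC splits into high-grade serous carcinoma (HGSC) and non-HGSC (clear
cell, mucinous, low-grade serous, endometrioid), two groups with
different carcinogenesis, prognosis and treatment. Deciding the subtype
currently requires surgery or biopsy. Radiomics asks whether the
contrast-enhanced CT image already carries the answer: thousands of
mathematically defined features — shape, intensity histogram, and
gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM), computed
on the original image and on Laplacian-of-Gaussian and wavelet
transforms of it — are extracted from the segmented tumor and fed to a
feature-selection + classification pipeline.

This package implements that pipeline end to end for users who want to
study, stress-test, or reuse the method itself:

- **preprocessing** — 3σ intensity normalization (clip at μ±3σ, z-score)
  and through-plane reconstruction to 5-mm section thickness;
- **feature catalog** — 1288 features: 14 mesh-based 3-D shape
  descriptors plus 91 intensity/texture features (18 first-order +
  22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM) on each of 14 image
  types (original, LoG σ = 1..5 mm, 8 stationary-wavelet subbands), with
  fixed-bin-width discretization (width 25);
- **voted LASSO** — the selection procedure at the core: 100 stratified
  8:2 resamples; per resample a two-sided Mann-Whitney *U* filter
  (α = .05) followed by L1-penalized logistic regression at the 10-fold
  cross-validated λ; features are ranked by how many resamples selected
  them, the top 10% (≤ 20) are retained, and their coefficients are
  averaged across all resamples into weights w̄ⱼ;
- **radscore** — per patient, radscore = Σⱼ xⱼ·w̄ⱼ over the retained
  features;
- **evaluation** — a univariate logistic model P(HGSC | radscore),
  scored by AUC / accuracy / sensitivity / specificity with 10-fold CV
  inside each training cohort and aggregated over the 100 resamples;
- **agreement** — Dice similarity coefficient (DSC = 2|A∩B|/(|A|+|B|))
  studies of repeated segmentations, with 0.80 as the satisfactory bar;
- **synthetic cohort** — a phantom generator whose two classes reproduce
  the reported class sphericity distributions (HGSC 0.608 ± 0.082,
  non-HGSC 0.669 ± 0.066) by per-phantom bisection, and a feature-table
  simulator with planted discriminative features among exchangeable
  nulls (default: 665 patients, 65.6% HGSC).

Raw multicenter CT data are not publicly deposited, so the pipeline's
correctness is demonstrated on these synthetic inputs; see
`docs/methods.md` for what that does and does not establish.

## Worked example

```python
import ovradiomics as ov

# a labeled feature table: 665 patients, 100 features, 5 informative
table = ov.simulate_feature_table(ov.TableSimConfig(seed=55))

plan = ov.ResamplePlan(n_resamples=100, base_seed=5)
selection = ov.VotedLassoModel(table, plan=plan).fit()
print(selection.summary())

results = ov.evaluate_pipeline(table, plan=plan, selection=selection)
print(results.summary())
```

prints:

```
Voted LASSO selection
========================================================
resamples: 100  train fraction: 0.8
ever-selected pool: 43 of 100 features
retained: 5 (top 10%, cap 20)
--------------------------------------------------------
feature                          votes    avg coef
f0002                              100      0.8934
f0004                              100      0.8681
f0001                              100      0.8651
f0003                              100      0.8058
f0005                              100      0.4397
Radscore logistic model — resample-aggregated performance
================================================================
cohort       AUC            95% CI    acc   sens   spec
train      0.857     (0.855-0.858)  0.785  0.790  0.776
test       0.852     (0.845-0.858)  0.766  0.776  0.748
```

All five planted features (`f0001`–`f0005`) are voted to the top, each
selected in every one of the 100 resamples, and every null feature is
out-voted. The radscore logistic model generalizes: training and
testing AUC agree to 0.005 — the balance one expects when selection is
stabilized by voting rather than fitted to a single split. For image-based work, `generate_phantom` +
`extract_features` produce the same kind of table from NRRD/NIfTI
volumes, and the `ovrad` CLI chains the stages
(`simulate → preprocess → extract → select → evaluate`, or `run-all`).

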