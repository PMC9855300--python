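# Methods

This note documents the models, numerical choices and known limitations
of `ovradiomics`. The package implements a CT-radiomics subtyping
pipeline (HGSC vs non-HGSC epithelial ovarian carcinoma) and a synthetic
data generator that stands in for clinical CT volumes, which are not
redistributable.

## Preprocessing

**3σ normalization.** Interpreted as clip-then-z-score: with μ and σ the
whole-volume mean and standard deviation, each voxel becomes
`(clip(x, μ−3σ, μ+3σ) − μ)/σ`, bounding the output at exactly ±3. μ and
σ are computed over the full grid, not the tumor mask, because
normalization precedes any mask-restricted analysis. The operation is
idempotent up to tail clipping. A constant image has no well-defined
z-score and raises an error rather than silently returning zeros.

An optional `scale` factor (default 1.0) multiplies the z-scores. The
end-to-end pipeline uses `scale=100`: with the catalog's fixed bin width
of 25, the raw ±3 z-score range would collapse to a single gray level,
whereas ±300 yields ~24 levels — the familiar normalize-scale-100
convention in radiomics practice. Library users who pass unscaled
normalized images should set the bin width accordingly (≈ 0.1–0.25).

**Section-thickness reconstruction.** Only the through-plane (slice)
axis is resampled, to 5 mm by default; in-plane spacing is untouched.
Slices are modeled as slabs (`slice i` covers `[i·s, (i+1)·s)`, center at
the slab middle), the new grid tiles the same physical extent, images
are interpolated linearly and masks nearest-neighbor so they remain
binary and aligned with their image. Requesting a thickness coarser than
the whole extent is an error.

## Feature catalog (1288 features)

14 shape features from the original-geometry mask, plus 91
intensity/texture features on each of 14 image types:

| stage | count |
| --- | --- |
| shape (mask only) | 14 |
| image types | original + LoG σ∈{1..5} mm + 8 wavelet subbands = 14 |
| per image type | 18 first-order + 22 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM = 91 |
| total | 14 + 14 × 91 = **1288** |

The per-family counts are fixed so the total matches the published
catalog size; the 22-feature GLCM list omits the commonly deprecated
redundant entries (SumAverage, Dissimilarity) and MCC. Feature names
follow `<imagetype>_<family>_<feature>`.

**Discretization.** Fixed bin width (default 25), re-anchored to the
in-mask minimum per image type: bin index `floor((x − min)/w) + 1`, so
the occupied levels start at 1 and the level count is the index of the
brightest voxel.

**Shape.** Volume and surface area come from a marching-cubes
triangulation of the mask. The binary grid is smoothed with a Gaussian
of σ = 0.7 voxel before meshing at the 0.5 level: meshing the raw binary
grid inflates surface area by ~8% from the voxel staircase (a digital
sphere would measure sphericity ≈ 0.92 instead of ≈ 0.99), while σ = 0.7
brings a digital sphere to 0.987 and changes enclosed volume by ≈ 1%.
Masks too thin to survive smoothing (single voxels) fall back to the raw
binary mesh rather than failing. Sphericity is the closed form
π^(1/3)·(6V)^(2/3)/A; axis lengths (major/minor/least, elongation,
flatness) come from the principal components of the voxel-center point
cloud; maximum diameters from convex-hull vertex distances of the mesh
(2-D variants on the projection dropping one axis).

**Filters.** LoG σ is in millimeters, converted through the image
spacing, and the response is scale-normalized (×σ²) so blob responses
are comparable across the bank; the implementation is Gaussian smoothing
followed by an exact discrete Laplacian (per-axis second differences
weighted by 1/spacing²), which is identically zero on constant images —
a property a truncated Gaussian-derivative kernel does not have. The
wavelet stage is a single-level stationary (undecimated) transform with
the short orthogonal `coif1` filter, chosen so all 8 subbands stay on
the input grid and aligned with the mask; odd-sized axes are edge-padded
to even and cropped back.

**Texture aggregation.** All families use 3-D 26-connectivity (13
direction offsets at distance 1). GLCM: symmetric co-occurrence
matrices, normalized per direction, averaged over directions. GLRLM: run
matrices summed (merged) over directions before feature computation;
RunPercentage divides by 13·N accordingly. GLSZM zones are 26-connected
components of equal gray level. GLDM uses α = 0 (dependence = number of
identical neighbors + 1). Degenerate cases are given conventional
values: Correlation = 1 on a constant region, NGTDM Coarseness = 1e6
when no gray-tone differences exist.

## Voted-LASSO selection

Per resample r = 1..100 (seeds derived from one base seed via
`SeedSequence`): a stratified 8:2 split (per-class training count
`round(n_c × 0.8)`); features standardized by the training mean/SD
(training-constant columns dropped with a warning); a two-sided
Mann-Whitney U filter at α = .05 on the training portion; L1-penalized
logistic regression on the survivors at the λ minimizing 10-fold
cross-validated deviance (12-point log grid, λ ∈ ~[3·10⁻⁵, 10⁻²·n⁻¹]
per-sample scale). "Selected" = nonzero coefficient. Nothing from the
held-out 20% touches selection.

Votes are tallied across resamples; features are ranked by vote count
(ties: larger mean |coefficient|, then name), the top
`ceil(0.10 × pool)` capped at 20 are retained, and each retained
feature's coefficient is averaged **over all resamples** (zeros included
when unselected), so the averaged weight w̄ⱼ encodes both effect size
and stability. Averaging only over selected resamples is available as
`coef_average="selected"`.

The radscore is Σⱼ xⱼ·w̄ⱼ over the retained features. Because w̄ lives
on the standardized scale, the fitted results store the pooled
feature means/SDs and apply them when scoring new patients
(`VotedLassoResults.radscore`); the free function `radscore()` is the
raw dot product for pre-standardized inputs.

## Evaluation

A univariate logistic model P(HGSC | radscore), fitted by maximum
likelihood (statsmodels); perfect separation falls back to a mildly
ridge-penalized fit (flagged, warned). For each resample: the training
estimate pools stratified 10-fold out-of-fold predictions within the
training cohort; the operating point is Youden's J on that pooled
training ROC; the train-fitted model and threshold are then applied once
to the held-out 20%. AUC uses midranks, so it equals U/(n₁n₂) exactly,
ties included.

Metrics are aggregated over the 100 resamples two ways:

- `ci95` — the 95% CI of the mean (normal approximation, SD/√R). This
  interval narrows as resamples are added and reproduces the very tight
  intervals a 100-resample ensemble yields (widths of a few 10⁻³).
- `spread95` — the 2.5–97.5 percentile range of the per-resample
  values, i.e. the between-resample variability itself, which does not
  shrink with R.

One caveat the architecture imposes: the averaged coefficients pool
selection information across all resamples, and every patient is in the
training portion of ~80% of them. On truly null data the *training*
AUC therefore sits slightly above 0.5 (≈ +0.02 observed); the held-out
estimates remain centered on chance. The same mechanism means selection
frequencies measure in-sample evidence within the one dataset at hand,
not reproducibility across datasets: a single null feature that happens
to separate the classes in the full data (among 100 nulls, minimum
p < .01 in most tables) will be re-selected in well over half the
resamples. Voting protects against split-to-split instability, not
against dataset-level false positives.

## Segmentation agreement

DSC = 2|A∩B|/(|A|+|B|); symmetric, 1 for identical non-empty masks. One
empty mask is a total miss (DSC 0, the standard convention); two empty
masks leave the coefficient undefined and raise. The study design
(which cases, which observer/repeat pairs) is a pairing-plan argument,
so intra- and interobserver comparisons of any cohort subsample are
expressed the same way; means are flagged against the 0.80
satisfactory-reproducibility bar.

## Synthetic data

**Phantoms.** Each tumor is a star-convex solid: an ellipsoid (mild
random axis ratios, geometric-mean radius 0.24 × grid extent; default
grid 56³ at 1 mm) whose radius is modulated by a smooth random angular
field (trigonometric series up to order 8, azimuthal terms damped at the
poles), optionally stretched up to ~3× along a random axis. One
irregularity parameter drives lobulation depth and elongation together
and is tuned per phantom by bisection (tolerance 0.01, ≤ 14 iterations)
until the measured mesh sphericity matches a target drawn from the
class distribution — N(0.608, 0.082²) for HGSC, N(0.669, 0.066²) for
non-HGSC, truncated to [0.42, 0.92]. An angular field whose reachable
range misses the target is redrawn (up to 10 attempts). At n = 200 per
class the sample means land within ±0.02 of the configured means.
Intensities are smoothed Gaussian fields in Hounsfield-like units
(tumor mean 50 HU; background 20 ± 10 HU). The classes also differ in
texture heterogeneity (in-mask SD 45 HU for HGSC vs 30 HU for
non-HGSC) — a free parameter of the generator: the source data only
establish the shape difference, and no claim is made that real HGSC
texture differs this way.

**Feature tables.** Unit-variance equicorrelated Gaussian features
(default pairwise correlation 0.1); the first `n_informative` features
get a standardized mean shift in the HGSC class (defaults: 5 features,
effects 1.0/0.9/0.8/0.7/0.6, chosen so the resample-aggregated test AUC
lands in the mid-0.8s — the performance regime of interest — while
leaving the nulls exchangeable). Labels use exact stratification
(`round(n × prevalence)` positives, default 65.6% of 665) for
reproducible class balance; Bernoulli draws are available.

**What passing tests show — and don't.** The synthetic cohorts verify
the machinery: catalog arithmetic, closed-form shape values, oracle
agreement (exact Mann-Whitney enumeration, AUC/U identity, LASSO
soft-thresholding), parameter recovery, and train/test balance. They do
not emulate scanner physics, multicenter acquisition variability,
inter-feature correlation structure of real radiomics panels, or
segmentation ambiguity, so they cannot certify clinical performance on
real CT data.

## Problem sizes and determinism

Default study sizes: 200 phantoms per class for sphericity recovery;
100-feature tables at n = 400 (selection calibration) and n = 665
(classification); 100 resamples throughout. Every stochastic component
(phantoms, tables, splits, CV folds) is driven by explicit integer
seeds; rerunning any stage with the same configuration is bit-identical.

## Known limitations

- The voted-LASSO null calibration discussed above: with 100 heavily
  overlapping resamples, a dataset-level false positive accumulates
  votes approaching 100; vote counts should not be read as a
  false-discovery control.
- Mesh smoothing trades a small volume underestimate (~1%) for accurate
  surface areas; extremely thin structures fall back to the raw mesh.
- The resampling of section thickness is slab-based along one axis;
  oblique acquisitions are out of scope.
- GLCM feature list reconstruction: the exact 22-feature inventory is a
  convention choice; any consistent 22-feature list preserves the
  catalog total.
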