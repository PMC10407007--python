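# Methods

This note records the models, conventions and numerical choices behind
`myotex`, in the order of the pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic LV phantoms

The cohort is emulated, not measured. Each phantom is built on a 64×64×32
voxel grid (6.6 mm isotropic, matching a 64-matrix cardiac SPECT
acquisition) as the difference of two half-ellipsoids — outer semi-axes
(22, 22, 13) and inner (13, 13, 8) voxels, with the top 30 % of the long
axis removed to mimic the open valve plane. Geometry is cosmetic; what
matters is a thick, connected, roughly LV-shaped ROI.

Uptake is `base × heterogeneity × defect`, then blurred and noised:

* **Heterogeneity field** — white noise smoothed by a Gaussian kernel of
  width `texture_corr_length` (voxels), re-standardized, scaled by
  `texture_sd` and exponentiated. A log-Gaussian field is the minimal
  positive model of spatially correlated uptake variation from mixed
  hibernating/scarred tissue — the signal the pipeline is supposed to read.
* **Defect** — a contiguous angular sector covering `defect_fraction`
  (default 0.15) of shell voxels, scaled by `defect_contrast` (default 0.6).
* **PSF** — Gaussian blur, `psf_sigma` = 1 voxel.
* **Noise** — Gaussian with standard deviation `noise_scale·√intensity`
  (default 0.5), a differentiable surrogate for Poisson count noise.

Class effect (the planted discriminating signal): classes 1/2/3 add
(0, 0), (1, 0.15), (2, 0.35) to (`texture_corr_length`, `texture_sd`) on a
base of (2, 0.10). Class sizes default to 24/12/16. These values were fixed
once, for testability: the source cohort is undeposited and gives no
quantitative within-class image statistics, so the defaults are chosen to
make the planted signal clearly present yet leave the null (all offsets
zero) exactly exchangeable. Passing tests therefore demonstrate that the
pipeline recovers a known planted heterogeneity effect — not that real
perfusion scans carry one. Per-sample seeds are `cohort_seed + index`.

The class effect touches correlation length and amplitude at once, so it is
broadly redundant across the texture families: many features separate the
classes, and a sparse selector's particular top set varies with the cohort
realization. The acceptance experiments therefore define "planted
discriminative feature" ground-truth-first: a feature qualifies if an
independent replicate cohort (same generator, different seed) confirms that
it separates classes 1 and 3 at p < 1e-3 — a screen that label-unrelated
features essentially never pass — and recovery means the selector's top 7
intersects that confirmed set.

## Preprocessing and segmentation

Normalization is min–max to [0, 1]; a constant image yields zeros with a
warning rather than an exception (batch robustness). Quantization is fixed
bin number over the in-mask range, `v → min(⌊L(v−min)/(max−min)⌋+1, L)` —
the standard dialect when intensities are already normalized.

Segmentation is two-stage: k-means on voxel intensities (k = 3:
background / blood pool and soft tissue / myocardium; seeded k-means++ with
10 restarts) keeps the highest-centroid cluster, then a morphological
Chan–Vese active contour (region-based snake; 10 iterations, smoothing 1)
refines each axial slice. The region-based flavor was chosen over an
edge-based geodesic snake because the phantoms (and perfusion SPECT
generally) have soft, blur-dominated boundaries where region statistics are
more stable than gradients; the contract is Dice-based either way. Both the
2D-per-slice and full-3D entry points exist; slice-wise is the default
because the 2D extractor consumes slices.

## 2D in-house battery (440 features/volume)

* Per-pixel GLCM: the slice is quantized once (whole-slice FBN, default 8
  levels), pair counts at distance 1 for 0°/45°/90°/135° are accumulated
  into one symmetric matrix per kernel position (rotation pooling), and 14
  Haralick statistics are computed — energy, contrast, correlation,
  variance, IDM, sum average/variance/entropy, entropy, difference
  average/variance/entropy, IMC1, IMC2. Difference average stands in for
  the numerically unstable maximal correlation coefficient. The fast path
  builds per-window counts from integral images over the pair-code one-hot
  cube and is tested for exact equality against the naive sliding-window
  route. Natural log for 2D entropies.
* LAWS: all 25 outer products of L5/E5/S5/R5/W5; texture energy = moving
  average of |response| over a 15×15 window (configurable).
* Gabor: wavelengths {2, 5.66, 8, 11.31, 22.63, 45.25} × 8 orientations
  (0°…157.5°) = 48 filters — a √2-spaced ladder; σ follows the one-octave
  bandwidth relation, kernels are truncated at 2.5σ (radius capped at 31
  px so the largest filters stay within the 64-px field of view), and the
  cosine part is DC-corrected so constant images give zero response.
  Responses are magnitude images, convolved via FFT with reflect padding.
* Median image: 3×3 running median, then the five statistics
  (`FO_<Stat>_ImgMed`).

Aggregation conventions, fixed package-wide: population variance,
Fisher–Pearson g1 skewness, non-excess kurtosis (normal → 3); constant
samples report skewness 0 and kurtosis 0 with a warning. Per-pixel kernels
use raw pixels even outside the ROI; the mask gates only center pixels.
Volume-level 2D features average the per-slice vectors over axial slices
with ≥ 25 ROI pixels.

## 3D battery (269 features)

Discretization: FBN, 64 levels by default. All texture matrices are built
on the ROI bounding box; entropies use log2.

* **First order (50)** — 18 intensity statistics, 25 intensity-histogram
  statistics on the discretized levels (the 18 plus mode, entropy,
  uniformity and the four histogram-gradient features, plus histogram
  energy and RMS), and 7 intensity-volume-histogram features. The 50-item
  roster is an explicit package decision recorded in
  `radiomics3d.feature_manifest()`; standard IBSI families alone sum to 48.
* **Morphology (29)** — mesh volume from raw-binary marching cubes
  (voxel-accurate) but surface area from a σ = 0.7-smoothed mesh: binary
  meshing inflates digitized-surface area by the voxel staircase (≈ +9 % on
  an r = 10 sphere) while light anti-aliasing removes that bias; with this
  split both the sphere volume and sphericity land within 2 % of analytic.
  Axis lengths from PCA; bounding densities for AABB, PCA-oriented box
  (OMBB approximation), approximating ellipsoid (Knud Thomsen area formula)
  and convex hull; integrated intensity; Moran's I and Geary's C with
  inverse-distance weights on a seeded ≤ 1000-voxel subsample.
* **GLCM (25×2), GLRLM (16×2)** — 13 unique 3D offsets;
  direction-merged matrices carry the plain name, direction-averaged get
  `_Avg`. Runs are found by per-level connected-component labelling with a
  direction-only structuring element.
* **GLSZM / GLDZM (16×2 each)** — zones by 26-connectivity (8 in 2D); zone
  distance is the minimum Chebyshev distance to outside the ROI with
  border voxels at distance 1 (the grid edge counts as border, enforced by
  zero-padding the distance transform). Full-3D carries the plain name,
  2D slice-averaged gets `_2D`.
* **NGTDM (5×2)** — 26-neighbour (8 in 2D) gray-tone difference;
  coarseness denominator guarded by ε = 1e−12 so constant ROIs stay finite.
* **NGLDM (17×2)** — dependence counts at Chebyshev distance 1 with
  α = 0; the matrix column for dependence count k is k+1, so an isolated
  voxel yields low-dependence emphasis exactly 1.

The dual aggregation is what reproduces the printed family counts
(25/16/16/16/5/17 × 2 = 50/32/32/32/10/34); the reference extractor's
actual aggregation settings are unpublished, so this reading is a
documented reconstruction, not ground truth. Every family is verified to
1e−9 against loop-based brute-force oracles (`tests/_oracles.py`) that
share no code with the vectorized implementations.

## Feature selection

z-scoring uses population SD and drops zero-variance columns with a warning
(on identical-geometry phantoms several morphology features are constant by
construction). NCA is the diagonal (per-feature-weight) variant: weighted
L1 distances `d_ij = Σ w_r²|x_ir − x_jr|`, L-BFGS on the expected
leave-one-out stochastic-neighbour objective with an L2 penalty; importance
is `w²/max w²` so the leading value is exactly 1. The penalty λ defaults to
a small grid {0.25, 0.5, 1, 2} scored on a seeded stratified 70/30 holdout
by stochastic-neighbour accuracy, ties broken toward stronger shrinkage so
label-independent data collapses toward zero weights. mRMR is the MID
(difference) variant with equal-frequency 8-bin discretization; when the
greedy stage is truncated at k the tail is ordered by plain relevance.
LASSO bisects the multinomial-logistic L1 path (saga) for the penalty whose
active set has the requested size, warning when only a nearest size is
achievable. The Wilcoxon rank-sum test is exact for two untied groups of
≤ 10, otherwise a tie- and continuity-corrected normal approximation.
Selection runs inside each training split by default; `paper_mode`
replicates full-cohort selection for comparability with small-cohort
radiomics practice (that is also what the report tables use, since they
describe one fixed feature set).

## Classifier evaluation

Hyperparameters are explicit because the original presets name no values:
fine KNN = 1-NN Euclidean; cosine KNN = 10-NN cosine; subspace KNN = 30 ×
1-NN on random feature subspaces of half the dimensions; cross-entropy tree
= single tree, log-loss criterion, no depth cap; RUSBoost = 30 SAMME-style
rounds of depth-3 trees on per-round class-balanced undersamples, learning
rate 0.1; cubic SVM = one-vs-one 3rd-degree polynomial kernel, C = 1,
class scores from softmaxed decision values; random forest = 100 trees, √d
features per split. KNN scores are neighbour-vote fractions so AUC is
defined everywhere.

Two repetition schemes exist because the protocol is described both as
10-fold cross-validation and as a fixed 46/6 stratified split: `holdout`
(default; 2 per class validation, stratified within-class bootstrap of the
training portion, matching the more specific 46/6 statement) and
`full-coverage` (stratified partition, every sample predicted once per
repetition, confusion rows summing to class sizes). Undefined metric ratios
report 0 with a flag so averages stay well-defined. One caveat the tests
respect: with a *fixed* random labeling, 1-NN's holdout hit rate
concentrates at a dataset-specific value whose repetition SE understates
labeling variance, so null calibrations average over independent label
permutations rather than relying on a single permuted cohort.

## Consensus clustering

Average (UPGMA) linkage throughout; distance = 1 − Pearson correlation
between sample vectors over the selected features (which is blind to
constant offsets — separability must live in the feature *pattern*, as it
does for z-scored selected features). Each of 1000 iterations subsamples
80 % without replacement and cuts at k = 3; consensus = co-cluster count /
co-sample count; the final assignment clusters 1 − consensus. Cluster-class
agreement is canonicalized by maximum-agreement (Hungarian) matching, so it
is invariant to cluster relabeling.

## Problem sizes in the checks

The acceptance experiments use the generator's default conditions: the
planted cohort at full 64×64×32 geometry (n = 52), the null cohort on a
32×32×16 grid, 100 seeded NCA runs, 25 evaluation repetitions, and 1000
consensus iterations. Oracle comparisons run on 4×4×4 fixtures where
exhaustive enumeration is exact.

## Known limitations

* Phantoms share one geometry; morphology features are non-informative (and
  partly constant) by design, which real cohorts would not be.
* The emulation collapses acquisition physics (projection, FBP
  reconstruction, attenuation, gating) into blur + noise.
* The 50-feature first-order roster and the dual-aggregation reading of the
  3D battery are reconstructions of an under-specified reference; counts
  match, individual definitions may not.
* Cohort-specific published values (per-class metric tables, consensus
  agreement percentages, feature p-values) depend on the unavailable
  patient data and are treated as plausibility references only.
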