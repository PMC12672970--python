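# Methods

This note documents the models, defaults and design choices behind
`habitatrisk`, and what the synthetic phantoms do and do not establish.

## Habitat discovery

**Over-segmentation.** Superpixels/supervoxels are produced by K-means in
the joint (intensity, compactness-scaled coordinate) space, seeded on a
regular grid inside the ROI with post-hoc connectivity enforcement (the
SLIC construction; `skimage.segmentation.slic` with a mask). Spacing is
passed as *relative* anisotropy (divided by its minimum): only the aspect
ratio of the voxels should influence the colour/space balance, not the
absolute millimetre scale. Defaults: 100 superpixels (2D), 150
supervoxels (3D), compactness 0.2. CT volumes are first clipped to the
soft-tissue window [−100, 200] HU and min-max scaled; this window is a
config constant, robust to calcification outliers. A size-3 median filter
despeckles ultrasound before over-segmentation; it is edge-preserving,
which matters — Gaussian smoothing (plain or log-domain) blurs class
boundaries into gradient bands that over-segment poorly.

**Profiles and weighting.** Each superpixel contributes (mean, SD, 32-bin
entropy, contrast, centroid); supervoxels contribute (mean HU, SD,
entropy). Columns are z-scored, then the non-mean columns are
down-weighted: texture 0.1 and coordinates 0.25 (2D), secondary columns
0.1 (3D). The mean intensity is the phenotype being clustered;
z-scoring a nearly constant SD column would otherwise amplify its noise
to unit variance and let it dominate the metric. The weights are part of
the clustering definition, exposed as parameters.

**Habitat clustering and model selection.** K-means (10 restarts,
k-means++ seeding, tol 1e-6, ≤ 300 iterations) for each candidate K;
the Calinski-Harabasz index CH = [B/(K−1)]/[W/(n−K)] selects K, ties
breaking toward the smaller K. K may be pinned (e.g. 4 for ultrasound,
5 for CT) to mirror a cohort-wide convention. Habitat ids are renumbered
by descending mean intensity/HU so "habitat 2" is a reproducible rank.
Zero within-cluster dispersion returns a capped sentinel (1e12).

**Two-stage CT clustering.** Stage 1: per-patient K-means into
`k_stage1 = 6` local clusters (patients with fewer supervoxels are
clustered at their supervoxel count, with a logged warning). Stage 2:
all local-cluster centroids, weighted by member voxel volume, are
K-means-clustered into the population palette; the weighting prevents
tiny clusters from steering the palette. `select_k_final` scores each
candidate K by the CH index of the pooled supervoxel profiles labelled
with their inherited population habitat — scoring on the sparse stage-2
centroid cloud instead rises monotonically in K and always over-selects.
A CH curve whose relative dispersion (CV) across candidates falls below
0.15 flags the selection as low-confidence: that flat profile is the
signature of a cohort without habitat structure (K-means will partition
a structureless Gaussian blob regardless, so the curve never collapses
to exactly flat).

## The 120-feature Multi-Scale Index

The vector is fixed-length with group sizes (4, 5, 5, 10, 5, 15, 15, 15,
20, 20, 6); absent habitats contribute zeros to count features and
zero-with-flag to intensity statistics. Conventions:

* All spatial interactions use face (6-) adjacency; pair co-occurrences
  count each unordered adjacent voxel pair once, in the order H1H2, H1H3,
  H1H4, H1H5, H2H3, H2H4, H2H5, H3H4, H3H5, H4H5. Border voxels are
  habitat voxels with at least one face neighbour outside the tumor mask
  (the array boundary counts as outside).
* The GLCM (MSI 1–4) is computed on the habitat labels themselves (five
  gray levels), distance 1, accumulated over the 13 unique 3D directions
  restricted to in-ROI pairs, symmetrized and normalized; the statistics
  are the canonical Haralick quartet (contrast, correlation, energy,
  homogeneity). A single occupied level reports correlation 1.
* Texture bank: slice-wise Gabor magnitude (frequency 0.15 cycles/pixel,
  four orientations averaged), single-level 3D Haar detail-energy
  fraction on the habitat bounding box (non-members filled with the
  habitat mean so edges do not leak), and uniform 8-neighbour LBP
  histogram entropy on 8-bit-quantized slices.
* Morphology: surface area is the exposed-face count weighted by the
  physical face areas (exact for boxes); convexity is voxel volume over
  the convex hull of the voxel-corner lattice; sphericity
  π^{1/3}(6V)^{2/3}/A uses a marching-cubes mesh area, which converges
  to the smooth-surface limit — a staircase face count would bias the
  sphericity of a ball low by roughly one third.
* Moments are population SD, skewness g1 and excess kurtosis g2
  (Gaussian → 0); habitats with < 2 voxels or zero variance report 0
  with a flag.
* Complexity: Shannon entropy (bits, 64 bins over the habitat's own
  range), box-counting fractal dimension (power-of-two boxes up to half
  the padded cube, least-squares slope), connectivity = 1/#26-connected
  components, eccentricity √(1 − λ_min/λ_max) of the coordinate
  covariance.
* The six global descriptors are declared constructions, not
  reconstructions of any published formula: habitat-fraction entropy;
  mean over window sizes {3, 5, 9} of the variance of the local
  majority-habitat fraction (windows normalized to in-ROI voxels);
  fraction of the 10 pairs with nonzero co-occurrence; total border
  interaction over volume; the L2 norm of the normalized-volume vector;
  and the mean of the first three after scaling each to [0, 1] by its
  attainable range (entropy by log₂5, the variance of a fraction by 1/4).
* ε = 1e-12 guards every ratio. Extraction refuses habitat maps whose
  mean intensities are not non-increasing in habitat id, enforcing the
  palette convention upstream.

The Fisher-score ranking uses per-class sample variances and keeps
features with F > 1.0 by default.

## The 635-feature radiomics bank

Intensities are min-max normalized to [0, 255] over the habitat region.
The bank is: original image → 19 first-order + 10 shape(2D) + 24 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM (104 features); nine derived
images (stationary Haar sub-bands LL/LH/HL/HH, Laplacian-of-Gaussian at
σ = 1, 2, 3 px, Gaussian gradient magnitude at σ = 1, squared intensity)
→ 19 first-order + 24 GLCM + 16 GLRLM each (531 features). Texture
discretization: fixed bin width 25 on the original image, fixed 32 bins
on derived images (whose dynamic ranges are arbitrary). Matrices use
distance 1 and merge the four unique 2D directions; runs and zones break
at region boundaries. The configuration is SHA-hashed into each block's
provenance so differently-configured blocks cannot be merged silently.

## Selection chain

Mann-Whitney U (two-sided, midranks; constant features report p = 1 and
drop) at α = 0.05 → greedy Spearman filter at |ρ| > 0.90 visiting
features by ascending p so only the most significant member of a
correlated group survives → logistic LASSO over a bounded penalty grid
C ∈ [10⁻³, 10] (beyond that the path approaches the unpenalized fit and
is not a selection regime), penalty chosen by stratified 10-fold
cross-validated deviance at its minimum. The deviance minimum retains
the most signal for downstream fusion but over-selects relative to the
sparser one-standard-error rule, which is available as `rule="1se"`.
Identical seeds give identical folds and therefore identical selections.

## Clinical screening

VIF removal is iterative — recompute after each removal, drop the worst
offender above 5, ties broken by column name so the screen is invariant
to column order; perfect collinearity carries an infinite sentinel and
goes first. The logistic fit standardizes continuous covariates by
default so ORs read per SD (binary covariates enter as-is); Wald CIs are
exp(β ± 1.96 SE). (Quasi-)separation is surfaced as a non-convergence
flag (Newton failure falls back to BFGS; huge or undefined standard
errors also trip the flag) — never silently returned. ICC(2,1) is the
two-way random-effects, absolute-agreement, single-measure coefficient
from the ANOVA mean squares, with the McGraw-Wong F-based interval.

## Models, fusion, evaluation

Defaults (none dictated by any report; all exposed): RF 500 trees; GBM
300 trees, depth 3, learning rate 0.1; KNN k = 7; SVM RBF C = 1 with
built-in probability calibration; LR unpenalized-ish (sklearn default);
NN a one-hidden-layer (width 64) perceptron that stops on a
training-loss plateau — validation-based early stopping is unreliable at
desk-scale n, where a 10% validation split holds a handful of subjects.
The NN is the tabular stand-in for a convolutional network whose
architecture is unreported; all learners sit behind a per-block z-scoring
pipeline. Late-weighted fusion derives its weights from inner 5-fold
cross-validated member AUCs, normalized to sum 1. Early fusion refuses
misaligned subject indices rather than reindexing.

AUC is the Mann-Whitney rank statistic with midrank ties (equal to
trapezoidal ROC integration on tie-free data); the default operating
threshold is 0.5 with a Youden-optimal alternative; the decision-curve
grid is 0.01–0.80 in steps of 0.01. DeLong's test uses placement-value
covariances; identical predictions report z = 0, p = 1. `kfold_cv` takes
the entire fit-and-predict pipeline as a callable so scaling, selection
and model fitting are refit inside each training fold — the leakage
contrast (in-fold vs whole-data selection on pure noise) is part of the
test suite. Permutation attribution (mean AUC drop over column
permutations) stands in for Shapley-value attribution.

## Synthetic phantoms: what they emulate, and what they do not

* **Ultrasound**: a smoothed-threshold Gaussian-random-field blob ROI
  (10–50% of the frame), partitioned into k contiguous, roughly balanced
  Voronoi patches (K-means on ROI coordinates) with strictly ordered mean
  echogenicities on [60, 220], modulated by multiplicative Rayleigh-like
  speckle (fractional SD `speckle_sigma`, default regime 0.2). Balanced
  patches mirror the near-balanced habitat compositions of real lesions;
  random-site Voronoi routinely produced classes too small to segment.
* **CT**: ellipsoidal lesions whose ROI holds k contiguous patchy density
  classes drawn from a cohort-shared palette on [−40, 160] HU plus
  additive Gaussian noise (default SD 5 HU). The patch scale is well
  above the supervoxel scale, emulating macroscopic compartments (solid,
  cystic, calcified) rather than voxel noise.
* **Clinical**: CLT ~ Bernoulli(0.242), tumor size ~ log-normal matched
  to 1.1 ± 0.8 cm, PLR ~ log-normal matched to 238.1 ± 146.9, two null
  nuisance covariates; the label is Bernoulli(logistic(β₀ + βᵀx)) with
  default log-odds ln 1.622 (CLT), ln 1.554 (size), ln 1.602 (PLR per
  SD) and β₀ solved by bisection for prevalence 0.473.
* **Multimodal blocks**: independent Gaussian per-modality signals
  calibrated through the binormal identity AUC = Φ(d/√2), used for the
  fusion and leakage studies.

The phantoms establish *recoverability and correctness* — that the
pipeline finds planted structure, counts interactions exactly, controls
type-I error and does not leak — not clinical performance. Real lesions
have habitats without sharp boundaries, spatially correlated speckle,
partial-volume effects and acquisition variability that these generators
deliberately omit; headline AUCs on real cohorts cannot be inferred from
phantom results.

## Problem sizes

The shipped tests and the acceptance script use 256² ultrasound frames,
48³ CT volumes with 10-patient cohorts, n = 5000 clinical cohorts,
1000–2000 null replicates for calibration and 10 seeds for the fusion
medians — sizes at which every planted-truth check is stable from seed
to seed on a single CPU.

## Known limitations

* The habitat count selector assumes habitats are separable in the
  profile space; habitats defined purely by higher-order texture at
  equal mean intensity would require re-weighting the profile columns.
* The radiomics bank is 2D; CT habitats get spatial (MSI) features
  instead of a 3D radiomics bank.
* GLSZM/GLDM/NGTDM are computed only on the original image — on filtered
  images their zone/dependence structure is dominated by filter support,
  not tissue.
* The ICC interval uses the F approximation; it degenerates at ICC → 1.
* Decision curves are reported without recalibration; the Brier score is
  the only calibration summary.
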