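# habitatrisk

Tumor *habitat imaging* for preoperative recurrence-risk stratification.
Intratumoral heterogeneity is clinically meaningful but invisible to
whole-lesion statistics: a papillary thyroid carcinoma that mixes
hypoechoic proliferative tissue with fibrotic and calcified compartments
behaves differently from a homogeneous one with the same mean intensity.
`habitatrisk` implements the full analysis chain that turns routine imaging
and blood work into a binary low vs intermediate/high-risk prediction:

1. **Habitat discovery.** The lesion ROI is over-segmented into
   superpixels (2D ultrasound) or supervoxels (3D CT) — K-means in the
   joint intensity/coordinate space with grid seeding and connectivity
   enforcement. Superpixel profiles are clustered into K habitats; K is
   chosen by the Calinski-Harabasz index CH = [B/(K−1)] / [W/(n−K)] or
   pinned (four habitats on ultrasound, five on CT are the usual working
   conventions). CT habitats are cohort-consistent via two-stage
   clustering: per-patient K-means, then volume-weighted K-means of the
   pooled local centroids into one population palette, ordered by
   descending mean HU.
2. **Spatial-heterogeneity features (MSI).** A fixed 120-element
   Multi-Scale Index vector per tumor: habitat-label GLCM statistics,
   habitat volumes, habitat∩border and pairwise co-occurrence counts
   (face adjacency), their volume-normalized forms, Gabor/wavelet/LBP
   texture, surface area/convexity/sphericity, intensity moments,
   entropy/fractal/connectivity/eccentricity, and six global architecture
   descriptors. Discriminative features are ranked by the Fisher score
   F = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] / (s²₊ + s²₋ + ε), threshold 1.0.
3. **Habitat radiomics.** A pinned 635-feature 2D bank per ultrasound
   habitat (first-order, shape, GLCM/GLRLM/GLSZM/GLDM/NGTDM on the
   original image; first-order + GLCM + GLRLM on wavelet, LoG, gradient
   and square-transformed images), filtered by Mann-Whitney U
   (p < 0.05) → Spearman correlation (|ρ| > 0.90) → logistic LASSO with
   stratified 10-fold cross-validation.
4. **Clinical screening.** Iterative VIF > 5 multicollinearity exclusion
   and multivariate logistic regression reported as OR with 95% Wald CIs;
   ICC(2,1) for inter-rater segmentation agreement.
5. **Multimodal fusion and evaluation.** Six learners (RF, GBM, NN, KNN,
   LR, SVM) over feature blocks; early fusion (concatenation), late fusion
   (averaged or AUC-weighted probabilities) and ensemble soft voting.
   Evaluation: accuracy/AUC/sensitivity/specificity/PPV/NPV/F1/Brier,
   DeLong's test for paired AUCs, decision-curve analysis
   NB(pₜ) = TP/n − (FP/n)·pₜ/(1−pₜ), and leakage-safe stratified k-fold
   cross-validation that refits selection inside every training fold.

Because clinical imaging cohorts are rarely shareable, the package ships a
first-class synthetic-phantom module (`habitatrisk.phantoms`) generating
speckled ultrasound lesions, CT lesion cohorts with a shared density-class
palette, and clinical tables with a known logistic risk model — every
stage of the pipeline is testable against planted ground truth.

## Worked example

```python
import numpy as np
from habitatrisk import phantoms
from habitatrisk.habitat_us import habitats_from_image

ph = phantoms.gen_us_phantom(k_classes=4, shape=(256, 256),
                             speckle_sigma=0.2, seed=1)
habmap, ch = habitats_from_image(ph.annotated(), k_range=range(2, 7), seed=0)
print("selected K =", habmap.n_habitats)
print("habitat fractions =", np.round(habmap.fractions, 3))
print("CH scores =", {k: round(v, 1) for k, v in ch.items()})
```

prints

```
selected K = 4
habitat fractions = [0.233 0.3   0.217 0.25 ]
CH scores = {2: 247.7, 3: 244.6, 4: 600.5, 5: 554.6, 6: 525.4}
```

The CH curve peaks at K = 4, recovering the four planted echotexture
classes (adjusted Rand vs ground truth: 0.997); habitat 1 is the most
echogenic compartment and the fractions are its area shares. The clinical
arm recovers its generating effects — on a synthetic cohort of n = 5000
generated with odds ratios 1.622 (CLT), 1.554 (tumor size) and 1.602
(PLR, per SD):

```python
cohort = phantoms.gen_clinical_cohort(5000, seed=1)
from habitatrisk.clinical import fit_multivariate_logistic
fit = fit_multivariate_logistic(cohort.table.drop(columns="label"),
                                cohort.table["label"])
print(fit.summary_frame().round(3))
```

```
             beta     OR  CI_low  CI_high      p
const      -0.226  0.797   0.746    0.853  0.000
CLT         0.445  1.560   1.362    1.787  0.000
tumor_size  0.455  1.576   1.473    1.687  0.000
PLR         0.507  1.660   1.552    1.776  0.000
age_z       0.037  1.038   0.979    1.100  0.209
nlr_z       0.007  1.007   0.950    1.068  0.804
```

Each fitted 95% CI brackets its generating value and the nuisance
covariates stay null. A command-line interface mirrors the library
(`habitatrisk simulate | segment-us | segment-ct | msi | select |
clinical | train | evaluate`).

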