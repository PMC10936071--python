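# Methods

`lesionhet` quantifies *inter-tumor* (lesion-to-lesion, spatial)
heterogeneity in patients who carry one primary tumor plus several
metastatic implants on co-registered PET/CT, and uses those metrics in
penalized Cox survival models. This note records the models, conventions
and design choices, and what the synthetic phantom cohort does and does
not establish.

## VOI inclusion and conventional measurements

A lesion (volume of interest, VOI) enters the analysis only if its mask's
axis-aligned bounding box exceeds 5 mm in **every** dimension (strict
inequality), and within each anatomical region only the lesion with the
largest voxel count is kept. "Largest" is volume (voxel count), not axis
length — volume is the conventional radiomics size proxy. The primary
lesion is subject to the same size rule. A patient with fewer than two
surviving lesions (primary + ≥ 1 implant) is excluded: inter-tumor
statistics are undefined for solitary disease.

Eight measurements per VOI:

| symbol | definition |
|---|---|
| Pixel_number | voxel count of the mask |
| Maj, Min | major/minor principal-axis lengths (mm) |
| HU | arithmetic mean CT value over the mask |
| SUVmax / SUVmean | max / mean SUV over the mask |
| SUVpeak | max over masked voxels of the mean SUV in a 1 cm³ sphere (r ≈ 6.2 mm) centred there, sphere clipped to the mask (EANM-style definition) |
| TLG | SUVmean × metabolic volume (mL); the whole mask is the metabolic volume — no %SUVmax sub-thresholding (a documented reading; thresholded variants are out of scope) |

Axis lengths come from the eigen-decomposition of the physical-coordinate
covariance of the masked voxels, reported as `2·sqrt(5·λ)`. That constant
is exact for solid ellipsoids in 3-D (a uniform ball of diameter *d* has
per-axis variance *d*²/20); the familiar `4·sqrt(λ)` constant is the 2-D
disk convention and underestimates 3-D diameters by ~11%.

## The 104 conventional heterogeneity metrics

For each of the 8 measurements, 13 statistics are computed **across a
patient's lesions** (n = number of lesions, ≥ 2), giving 104 named
metrics (`SUVmean_CV`, `HU_SM`, …) in a fixed column order. Conventions
(the statistic names do not pin down formulas, so these are declared and
oracle-tested):

* `Variance`, `Std_dev`, `SM` (standard error of the mean) use the sample
  divisor n − 1.
* `Skewness` = m₃/m₂^1.5 and `Kurtosis` = m₄/m₂² − 3 (excess) with
  population moments m_k = Σ(x−mean)^k/n, so both exist from n = 2 and are
  0 for constant input.
* `R` is the quartile deviation (Q₃ − Q₁)/2 with linear-interpolation
  quantiles; `Median` uses the midpoint convention.
* `Mode` on continuous data: round to 4 significant digits, most frequent
  value, ties broken toward the smallest. Deterministic, but inherently
  the least stable statistic (for all-distinct values it degenerates to
  the minimum) — visible in the reproducibility screen below.
* `CV` = Std_dev/|mean| (0 when the mean is 0), not percentified;
  `CSS` = Σ(x−mean)², `USS` = Σx² (so USS = CSS + n·mean² identically).

## The 3 texture heterogeneity metrics (cSE, cluDev, cluDiss)

CT-only, per patient:

1. **Discretization.** Masked HU values are min–max rescaled per lesion to
   256 integer grey values and binned with width 32 → G = 8 levels. The
   per-lesion min–max makes every texture quantity invariant under
   constant HU shifts of a lesion.
2. **GLCM.** 3-D grey-level co-occurrence matrix at distance 1 over the 13
   unique offsets, both voxels in-mask, symmetrized, merged over offsets,
   normalized.
3. **Haralick features.** Energy Σp², entropy −Σp·log₂p (bits), contrast
   Σ(i−j)²p, homogeneity Σp/(1+|i−j|) per lesion; logged as intermediates.
4. **Subregion clustering.** Per-voxel features (grey level, 3×3×3 local
   mean, 3×3×3 local SD), z-scored within the lesion, partitioned by
   k-means (k = 3, 10 restarts, one shared seed for all lesions so the
   extraction is a deterministic function of the images). A lesion's
   *texture signature* is the concatenation of its k lexicographically
   sorted centroids; degenerate lesions collapse to fewer effective
   subregions and the signature is padded by repetition.
5. **Cluster site entropy (cSE).** Pairwise Euclidean distances between
   the lesions' signatures are histogrammed into 10 equal-width bins over
   [0, max]; cSE is the entropy (bits) of the occupied-bin frequencies,
   with all-zero distances defined as 0. Building the dissimilarity
   matrix across *lesions* (not across pooled subregions) is deliberate:
   it makes cSE vanish exactly when all lesions are texture-identical,
   which a pooled-subregion variant cannot do for lesions with internal
   structure. The original procedure lives in an unavailable supplement;
   this is a documented reference surrogate behind the same contracts.
6. **GLDZM and cluDev/cluDiss.** Zones are 26-connected components of
   equal grey level; each zone is indexed by (grey level, minimum
   Chebyshev voxel distance of the zone to the mask border, border voxels
   at distance 1, outside-of-image counting as border). Distances are
   aggregated into 4 relative bands (quarters of the lesion's maximum
   border distance) so the G×4 zone-fraction vectors are comparable
   across lesion sizes. cluDiss is the mean and cluDev the population SD
   of the upper-triangle entries of the inter-lesion Euclidean distance
   matrix over those vectors.

All three metrics are ≥ 0, invariant to lesion relabeling and constant HU
shifts, exactly 0 on clone-lesion patients, and cluDiss rises
monotonically with planted between-lesion *texture* contrast. A planted
contrast in lesion **mean** HU is invisible by construction (min–max
rescaling removes it); the sensitivity sweep therefore plants differing
core/rim contrasts across lesions.

## Survival models

Three feature sets per endpoint (PFS, OS): **conventional** (clinical
covariates + primary-lesion measurements; FIGO stage and invasion pattern
ordinal, surgical status and ascites character one-hot, nodal/implant
flags binary; CA125 and ascites volume untransformed by default),
**heterogeneity** (the 107 metrics), **integrated** (union) — six models.
Columns are standardized to training-set mean 0 / SD 1; zero-variance
columns are dropped and logged; test rows always use training constants.

Fitting is L1-penalized Cox (coordinate descent over a 50-point
log-spaced penalty grid, `alpha_min_ratio` 0.01). The penalty is chosen by
5-fold cross-validation, folds stratified by event status, maximizing the
mean held-out **Breslow partial log-likelihood** (the λ_min rule — chosen
over λ_1se because the emulated study reports multi-feature models), then
the model is refit on the full training set. The risk score is the linear
predictor Σβ_j·x_j over the selected (nonzero) features. Breslow tie
handling is used throughout, including the unpenalized hazard-ratio fits
(Wald 95% CIs).

Evaluation: Harrell's C over usable pairs (score ties count ½) with a
seeded 1000-replicate bootstrap-percentile 95% CI (the CI method is a
package choice); Kaplan–Meier curves and the two-group log-rank test
after splitting at the **training-median** risk; IPCW cumulative/dynamic
AUC at 1–3 y (PFS) and 1–5 y (OS) horizons by default. Nomograms are
exported as coefficient/points tables rather than drawn.

## Agreement and correlation

H-score = %weak·1 + %moderate·2 + %strong·3 ∈ [0, 300]. Spearman's ρ uses
average ranks; its p-value is exact (full permutation enumeration) for
n ≤ 10 and the t approximation above. Correlations run only on patients
carrying stain data; no imputation. ICC forms: intra-observer →
two-way mixed, consistency, single measurement (ICC(3,1));
inter-observer → two-way random, absolute agreement, single measurement
(ICC(2,1)); the reliability screen flags metrics with ICC > 0.75.

## Synthetic phantom cohort

The generator emulates the study conditions end to end with known ground
truth; every draw is a pure function of (config, seed), with per-patient
substreams spawned by a counter-based key so cohorts are reproducible in
any order.

* **Anatomy.** One ellipsoidal primary (20–40 mm) plus k implants
  (k ~ uniform on 1–9, matching the reported median of ~6 implants) in
  distinct zones of the 9-region abdominopelvic code; isotropic 1 mm
  grid (the IBSI-style isotropic-resampling operating point; scanner
  slice thickness is not simulated). All lesions pass the 5 mm size
  filter by construction (implants ≥ 8 mm).
* **Intensities.** Per-lesion means drawn around patient-level HU/SUV
  bases with a patient-level lognormal dispersion multiplier — the true
  between-lesion heterogeneity — and filled with spatially correlated
  Gaussian noise (1.5–3 mm correlation length), SD normalized on the
  mask so each lesion hits its target noise SD exactly.
* **Covariates.** Category frequencies follow the published training-set
  tables (e.g. FIGO IIIC ≈ 57%, R0 ≈ 57%, non-bloody ascites ≈ 65%);
  age ≈ N(54, 9.4²); CA125 and ascites volume lognormal around the
  reported medians.
* **Survival.** Event time ~ Exponential(rate·exp(lp)) with default PFS
  median 650 d and OS median 1020 d at lp = 0 (the reported medians);
  censoring = min(Uniform(0, 6600 d), 2200 d administrative), giving
  ≈ 30% censoring (the source reports medians only, so the censoring
  mechanism is a declared default, not an inference). The planted linear
  predictor applies the configured β to **cohort-z-scored extracted
  metrics** (default: SUVmean_Std_dev and TLG_CV) plus clinical terms
  (FIGO, surgical status, CA125); planting on the extracted metric
  rather than a latent driver is what makes exact-feature recovery
  well-posed under LASSO, since dispersion statistics of the same
  measurement are nearly collinear.
* **H-scores.** A Gaussian copula couples the normal scores of the risk
  ranks to a latent stain variable; the latent Pearson correlation is
  pre-warped by 2·sin(πρ/6) so the *Spearman* correlation converges to
  the target (default 0.85). The latent maps monotonically to an H-score,
  which is decomposed into a random but exactly consistent
  (weak, moderate, strong) triple with total stained fraction ≤ 100%.
  Stains attach to ~31% of patients, the typical IHC coverage.
* **Segmentation perturbation.** A smooth random field, clipped at the
  magnitude, displaces the signed Euclidean distance to the lesion
  surface (voxel centres offset by half a voxel), dilating/eroding random
  boundary patches by up to the magnitude; ~1 mm on a 15 mm lesion gives
  Dice ≈ 0.86–0.92.

**What the phantoms do not show.** Lesions are ellipsoids with stationary
Gaussian texture: no irregular margins, cystic components, partial-volume
or reconstruction effects, and no anatomical coupling between region and
lesion phenotype. Passing tests demonstrate the *pipeline's* correctness
and the recoverability of planted effects under these conditions — not
clinical performance on hospital data, whose headline concordance and
correlation values are reporting contracts only.

## Problem sizes and numerical notes

Default verification sizes (package choices): planted-LASSO recovery uses
20 seeded cohorts of n = 300 (≈ 67% events); hazard-ratio recovery
n = 500; copula calibration n = 500 with a 200-replicate Monte-Carlo
check; the reproducibility screen uses 30 patients with 1 mm
perturbation. In that screen ≥ 95% of the 107 metrics exceed ICC 0.75
(observed 96–98% over seeds); the stragglers are consistently the
Mode-of-size metrics, whose tie-to-the-minimum convention is genuinely
boundary-sensitive — an honest property of the convention, retained and
documented rather than patched.

Degenerate inputs: constant lesions discretize to grey level 1 (with a
warning) and collapse to one effective subregion; single-voxel masks have
axis lengths (0, 0) with a warning; k-means k is reduced when a lesion
offers fewer distinct feature rows; an emptying mask perturbation retries
at half magnitude with a warning; a CV with zero mean, a Spearman ρ on a
constant vector, and an ICC with zero between-subject variance are 0,
an error, and NaN-with-warning respectively.
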