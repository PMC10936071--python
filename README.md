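# lesionhet

**Inter-tumor heterogeneity metrics and prognostic survival models for
multi-lesion PET/CT.**

Advanced high-grade serous ovarian cancer typically presents as one
primary tumor plus multiple peritoneal metastatic implants. The
variation *between* those lesions — inter-tumor (spatial) heterogeneity —
carries prognostic information that single-lesion radiomics ignores.
`lesionhet` is for imaging researchers who want to quantify that
variation on co-registered ¹⁸F-FDG PET/CT and feed it into survival
models:

* **104 conventional heterogeneity metrics** — for each of 8 per-lesion
  measurements (Pixel_number, Maj, Min, HU, SUVmax, SUVmean, SUVpeak,
  TLG), 13 cross-lesion statistics (Mean, Median, Mode, quartile
  deviation R, Std_dev, SM, Variance, Range, CV, CSS, USS, Kurtosis,
  Skewness), e.g. `SUVmean_CV = sd(SUVmean over lesions)/|mean|`;
* **3 CT-texture heterogeneity metrics** — cluster site entropy (cSE)
  from k-means texture-subregion signatures, and cluster standard
  deviation / cluster dissimilarity (cluDev, cluDiss) from inter-lesion
  distances between grey-level distance-zone-matrix (GLDZM) profiles;
* **LASSO-Cox models** (conventional / heterogeneity / integrated ×
  PFS / OS) with penalty chosen by event-stratified 5-fold
  cross-validated partial likelihood; evaluation by Harrell's C with
  bootstrap CIs, Kaplan–Meier + log-rank after a training-median risk
  split, and IPCW time-dependent ROC AUC;
* **Agreement tooling** — immunohistochemistry H-scores
  (%weak·1 + %moderate·2 + %strong·3), Spearman correlation of risk
  scores with p53/Ki-67 H-scores, and ICC-based test–retest screening of
  every metric (pass at ICC > 0.75);
* **A synthetic phantom cohort generator** with known ground truth
  (planted log-hazard effects, copula-calibrated H-scores, simulated
  segmentation perturbation), so the whole pipeline is testable without
  patient data.

VOIs must exceed 5 mm in every bounding-box dimension, one lesion per
abdominopelvic zone (AR-0…AR-8, largest kept); patients need the primary
plus at least one implant. See `docs/methods.md` for all conventions.

## Worked example

```python
import lesionhet as lh

config = lh.SimulationConfig(n_train=60, n_test=24, seed=11)
cohort = lh.generate_cohort(config)

patient = cohort.patients[0]
vector = lh.heterogeneity_vector(patient, lh.TextureConfig(seed=11))
print(vector[["SUVmean_Std_dev", "HU_SM", "TLG_CV", "cSE", "cluDev", "cluDiss"]])

het = lh.heterogeneity_table(cohort.patients, lh.TextureConfig(seed=11))
table = lh.models.assemble_feature_table(
    cohort.clinical_frame(), lh.lesion_measurement_table(cohort.patients),
    het, "integrated").fit_standardizer(cohort.train_ids)
out = cohort.outcome_frame("pfs")
fit = lh.models.fit_lasso_cox(
    table.transform(cohort.train_ids),
    out.time.loc[cohort.train_ids].to_numpy(),
    out.event.loc[cohort.train_ids].to_numpy(), seed=0)

scores = lh.models.risk_score(fit, table.transform(cohort.test_ids))
c, ci = lh.models.concordance_index(
    scores, out.time.loc[cohort.test_ids].to_numpy(),
    out.event.loc[cohort.test_ids].to_numpy(), seed=0)
print(f"test C-index {c:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f})")
```

prints (84-patient phantom cohort, patient `P0000` carries a primary and
9 implants):

```
SUVmean_Std_dev    1.387
HU_SM              4.103
TLG_CV             1.320
cSE                2.975
cluDev             0.151
cluDiss            0.405
test C-index 0.717 (95% CI 0.585-0.847)
```

`SUVmean_Std_dev = 1.387` says this patient's lesions disagree in mean
tracer uptake by ±1.4 SUV — high lesion-to-lesion metabolic
heterogeneity; `cSE = 2.975` bits means the pairwise texture
dissimilarities between lesions spread over many distance bins rather
than collapsing to one. The LASSO-Cox fit here keeps 5 of 141 candidate
features (uptake-dispersion metrics plus FIGO stage) and ranks unseen
test patients with C = 0.72; the fitted hazard ratio per unit risk score
on the test set is 5.1 (p = 0.007), i.e. higher inter-tumor heterogeneity
→ earlier progression.

A thin CLI mirrors the library:
`lesionhet simulate | extract | fit | correlate | icc` (see `--help`).

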