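# dynrad

Dynamic characterization of multi-phase DCE-MRI radiomics for treatment
response modelling, exercised end-to-end on synthetic phantom cohorts.

The package implements the full analysis chain:

1. **Synthetic cohort generation** — phantom 6-phase contrast series with a
   gamma-variate enhancement curve whose kinetics differ between a latent
   responder-like and non-responder-like class, clinical covariates (HR,
   HER2, treatment arm), pCR outcomes drawn from a logistic model, and a
   paired expression matrix with planted differentially expressed genes.
2. **Preprocessing** — pooled (all-phase) z-score normalization that
   preserves inter-phase enhancement dynamics, isotropic 1 mm resampling,
   fixed-bin-width discretization (IBSI convention), and an
   enhancement-threshold (FTV-style) masking operation.
3. **Radiomic features** — 110 IBSI-style features per phase: 14
   morphological, 17 first-order, and 79 texture features (GLCM 25,
   GLRLM 16, GLSZM 16, GLDM/NGLDM 17, NGTDM 5), all implemented in
   NumPy/SciPy with brute-force oracles in the test suite.
4. **Reliability screening** — mask-perturbation repeatability (one-way
   random-effects ICC, threshold 0.9 in every phase) and a phase-variation
   t test; survivors form phase-ordered feature series.
5. **Dynamics** — each series is summarized by the 22 canonical time-series
   characteristics (a faithful NumPy reimplementation, validated against
   the reference implementation to 1e-6; see `tests/test_catch22.py`).
6. **Modelling** — variance → Mann-Whitney → L1-logistic → mRMR selection
   cascade; logistic models with 10-fold CV prefix-size selection; combined
   models (C/R/D/CR/CD/RD/CRD) stacking out-of-fold component scores.
7. **Evaluation** — DeLong AUC CIs and paired tests, likelihood-ratio
   tests, Youden-threshold metrics, Brier/calibration, decision curves,
   subgroup odds ratios, exact linear SHAP.
8. **Radiogenomics** — DYN+/− stratification by the dynamic model,
   per-gene t tests with |log2FC| > 0.25 and p < 0.05 cutoffs, and
   phenotype-permutation GSEA with p < 0.05 / FDR < 0.25 significance.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria; criterion 4
runs the full default cohort (n = 785) and takes several minutes.

## CLI

```bash
dynrad config --show                       # print all defaults
dynrad simulate --out cohort/ --seed 1     # write NIfTI phases + CSVs
dynrad extract --in cohort/ --out features.csv
dynrad run --out results/ --seed 1         # full pipeline + reports
```

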