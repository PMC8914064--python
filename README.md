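# radionmf

**CT radiomics + nonnegative matrix factorization for pretreatment prediction of
BCG immunotherapy failure in non-muscle-invasive bladder cancer (NMIBC).**

High-risk NMIBC is treated with Bacillus Calmette-Guérin (BCG) instillation after
transurethral resection, but a large fraction of patients relapse. With only a
handful of failures in a typical cohort, supervised radiomics models overfit badly;
an unsupervised route is to factorize the radiomics feature matrix into a few
nonnegative *metafeatures* (analogous to metagenes in expression analysis) and ask
which one carries the prognostic signal. This package implements that analysis
end to end for researchers working on imaging biomarkers of treatment response:

1. **Feature extraction** — the 107 original-image radiomics features
   (14 shape, 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM)
   from a 3D CT volume + lesion mask (NIfTI), after resampling to 1×1×2 mm and
   fixed-bin-width (25 HU) grey-level discretization.
2. **Preprocessing** — assembly of the feature-by-sample matrix
   V (M×N), greedy removal of collinear features (pairwise Pearson |r| > 0.9), and
   per-feature min–max scaling to [0, 1].
3. **Factorization** — V ≈ WH with W (M×k) ≥ 0 the metafeature loadings and
   H (k×N) ≥ 0 the per-sample component levels, fit by the classic multiplicative
   updates for the Frobenius objective with many random restarts; the rank k is the
   bend (largest discrete second difference) of the best-of-restarts residual
   sum-of-squares curve over k = 2..10.
4. **Component selection** — each z-scored row of H is fit as the sole covariate of
   a Cox proportional-hazards model (Newton–Raphson, Efron ties) on recurrence-free
   survival; the component with the highest Harrell's C-index becomes the imaging
   risk score.
5. **Evaluation** — ROC/AUC, Youden-index cutoff, confusion metrics,
   Kaplan–Meier curves with the log-rank test, calibration at a 12-month horizon
   (Breslow baseline hazard), decision-curve net benefit, and ICC for segmentation
   reproducibility.

A first-class synthetic-data module generates lesion phantoms (analytic spheres,
ellipsoids, textured blobs) and cohorts with a planted low-rank structure in which
one component drives an exponential proportional-hazards failure process, so the
entire analysis runs and is tested without any patient data. Validation cohorts
are scored with training-frozen parameters only: retained feature list, scaling,
W (via nonnegative least squares projection), z-score parameters, and cutoff.

## Worked example

`examples/04_training_and_validation.py` trains on a synthetic training-like
cohort (104 samples, ~11% failure by 12 months) and validates frozen on a second
cohort drawn from the same planted feature dictionary (24 samples, ~46% failure):

```
training (N=104, 13 failures):
  rank k=5, selected component 3
  AUC 0.85, cutoff z=-0.22, sens 0.92, spec 0.74
  C-index 0.72, log-rank p 0.000
validation (N=24, 10 failures, frozen parameters):
  AUC 0.89, sens 0.80, spec 0.93, C-index 0.79
```

The factorization recovers the planted rank 5; the selected component is the one
whose per-sample level drives the simulated failure hazard; AUC/sensitivity/
specificity describe 12-month failure classification at the chosen z-score
cutoff, and the C-index summarizes how well the component ranks recurrence-free
survival. The other example scripts walk through phantom feature extraction
(`01`), RSS-curve rank selection (`02`), and Cox-based component screening (`03`).

A thin CLI mirrors the stages:

```bash
radionmf simulate cohort --seed 1 --out data/
radionmf run-all --features data/features.csv --clinical data/clinical.csv \
    --seed 42 --out results/
radionmf extract --image img.nii.gz --mask roi.nii.gz --spacing 1 1 2 \
    --bin-width 25 --out features.csv
```

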