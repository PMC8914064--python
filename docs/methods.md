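# Methods

This note documents the models, numerical choices, and design decisions behind
`radionmf`, and what the synthetic-data suites do and do not demonstrate.

## Radiomics feature extraction

**Pipeline.** Volumes are resampled to a working spacing of 1×1×2 mm (trilinear
for intensities, nearest-neighbour for the mask, with nearest-neighbour
extrapolation at the grid boundary so constant images stay constant). ROI
intensities are discretized with a fixed bin width of 25 HU,
`level(x) = floor((I(x) − min_ROI)/25) + 1`, the de-facto default for CT texture
analysis; binning is min-referenced, so every texture feature is invariant to
adding a constant to the image. The working spacing reflects typical axial CT of
the pelvis (sub-millimetre in-plane, thicker slices); both spacing and bin width
are configurable.

**Families.** The 107-feature original-image set: 14 shape, 18 first-order,
24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM, with family-qualified names in a
fixed order. Texture conventions: GLCM and GLRLM accumulate one matrix per
direction (the 13 unique 3D offsets at distance 1), compute features per
direction, and average; GLCM matrices are symmetric. GLSZM zones and GLDM/NGTDM
neighbourhoods use 26-connectivity. GLDM dependence counts include the centre
voxel (j ≥ 1), which keeps the small-dependence emphasis terms defined for
isolated voxels. First-order moments are population moments; Kurtosis is the
raw fourth standardized moment (not excess). Entropies use log2 with a
machine-epsilon guard.

**Shape.** Mesh-based quantities (mesh volume, surface area, sphericity, maximum
diameters) come from a marching-cubes isosurface at level 0.5. The binary
indicator is anti-aliased with a Gaussian of 1 voxel sigma before meshing:
marching cubes on a raw 0/1 grid produces a staircase surface whose area
overestimates smooth lesions by 5–10% and biases sphericity of a digital sphere
to ≈0.92; with anti-aliasing a radius-10 mm sphere measures sphericity 0.992–0.997
at clinically relevant spacings, at the cost of a few percent of mesh volume on
small lesions (voxel-counting volume is unaffected). Axis lengths are 4√λ from a
PCA of the physical voxel-centre coordinates; 2D maximum diameters are measured
between boundary-voxel centres within planes perpendicular to each axis.

**Degenerate ROIs** (single voxel or a single grey level) return closed-form
degenerate values (entropy 0, contrast 0, maximum probability 1, …), never NaN,
and emit a warning.

Because no reference radiomics extractor is a dependency, correctness rests on
independent oracles in the test suite: analytic sphere limits for shape,
closed-form first-order statistics, and exact agreement of every texture matrix
with brute-force voxel-loop reimplementations (plus skimage's co-occurrence
routine for GLCM on single-slice volumes).

## Preprocessing

Collinear features are removed greedily: while any pair has Pearson |r| above
the threshold (default 0.90), the member of the worst pair with the larger mean
absolute correlation to the remaining features is dropped (ties: the
later-declared name). Constant features are dropped first. The filter is
idempotent and invariant to sample order. Surviving features are min–max scaled
to [0, 1] per feature; the minima/maxima are frozen and later applied, with
clipping, to validation cohorts. Min–max scaling (rather than shifting by a
global minimum) keeps features on comparable scales so no single family
dominates the Frobenius objective.

## Nonnegative matrix factorization

Multiplicative updates for the Frobenius objective,

    H ← H · (WᵀV) / (WᵀWH + ε),   W ← W · (VHᵀ) / (WHHᵀ + ε),   ε = 1e-10,

initialized with entries uniform on (0, 1] scaled by mean(V); stopping when the
relative RSS change falls below 1e-6 or at 2000 iterations (defaults that
converge on all synthetic suites). The objective history is recorded and is
non-increasing at every iteration. After fitting, W columns are normalized to
unit Euclidean norm with the scale absorbed into H, which makes the per-sample
component levels — and hence the z-score cutoff applied to them — well defined.

**Rank selection.** For each k in 2..10, many random restarts (default 100;
restart seeds derive deterministically from (master seed, k, restart)) and the
best RSS is kept. The chosen rank maximizes the discrete second difference
rss(k−1) − 2·rss(k) + rss(k+1) over interior grid points — the bend of the curve
— with ties toward smaller k and a warning plus k_min on a flat curve. Restart
aggregation by best RSS was chosen over consensus clustering as the simplest
reading of "repeated factorizations"; the curve is bit-reproducible for a fixed
master seed.

**Scoring by projection.** Per-sample component levels used for survival
screening and classification are computed by nonnegative least squares
projection onto the trained W, for the training cohort as well as for
validation cohorts. A validation cohort can only ever be scored by projection;
using the same path for training guarantees that validating the training cohort
under frozen parameters reproduces the training metrics bit for bit, which the
pipeline asserts. (The factorization's own H is retained for RSS and
diagnostics; on well-fit data the two agree to ~1%.) Component scores are
z-standardized with population mean/SD across training samples; the parameters
are frozen for new cohorts.

## Survival screening and selection

Each z-scored component is the sole covariate of a Cox proportional-hazards
model fit by damped Newton–Raphson on the partial likelihood with the Efron tie
correction (month-granularity follow-up produces heavy ties; Breslow is
available by flag). Convergence at |Δβ| < 1e-8 or 50 iterations; a monotone
likelihood (perfect separation) yields a capped β (|β| = 20) with a warning
rather than an error. Harrell's C-index counts pairs (i, j) with t_i < t_j and
event_i = 1; score ties count 0.5. The component with the highest C-index is
selected (ties toward the smaller index). If the winner's C-index is below 0.5
its sign is flipped — recorded in the selection — so that a higher score always
means higher risk; a winner below 0.6 raises a low-signal flag. Selection uses
the training cohort only; no cross-validation is performed.

## Evaluation

Positive calls use score ≥ cutoff (inclusive boundary, chosen and applied
consistently in training and validation). The default cutoff policy maximizes
Youden's J over observed scores (smallest cutoff on ties); a fixed cutoff
(e.g. z = 0.2) may be frozen instead. AUC uses the Mann–Whitney formulation
with midrank tie handling. Kaplan–Meier is the product-limit estimator; the
median is the earliest time with S ≤ 0.5 (undefined if never reached). The
log-rank test is the standard two-group chi-square with hypergeometric
variance. Calibration bins samples into quantile bins (default 3, appropriate
for cohorts of ~100) of the model-based failure-by-horizon probability
1 − exp(−H₀(h)·e^{βx}) with the Breslow baseline cumulative hazard, and
compares the bin-mean prediction with the KM-observed failure fraction at the
horizon. Decision curves report net benefit TP/n − (FP/n)·p_t/(1−p_t) with
treat-all and treat-none references. ICC is the two-way, absolute-agreement,
single-measurement coefficient from the standard ANOVA decomposition. Log-rank
p-values are reported to 3 decimals; no multiplicity correction is applied to
the single pre-selected component.

## Synthetic data: what it emulates, and what it does not

**Phantoms** place an analytic sphere/ellipsoid, or a textured blob (ellipsoid
with its surface modulated by a smooth random field, amplitude 15% of radius),
on a voxel grid with physical spacing. Masks are exactly the voxels whose
centre lies inside the analytic surface. Intensities use urine-like background
(5 HU) and soft-tissue lesion (45 HU) defaults; the blob adds a correlated
intra-lesion texture field with peak amplitude equal to the lesion–background
contrast — a grey-level spread comparable to heterogeneous contrast
enhancement — plus optional Gaussian noise (3 HU is a typical CT noise level).
No scanner physics, beam hardening, contrast phases, or multi-lesion anatomy
are simulated.

**Cohorts** are V = W·H + noise, clipped at zero. Planted W: uniform loadings
with a configurable fraction (default 0.6) of near-zero entries per component,
columns norm-equalized so no planted component degenerates. Planted H is
archetypal: each sample is dominated by one component (balanced subtype sizes,
high level 0.7–1.0, background 0–0.25 elsewhere), mirroring the
radiomics-subtype picture the method assumes. This choice matters: with fully
uniform random H, rows are strongly cross-correlated through their shared mean,
the singular values decline smoothly, and the RSS curve has no identifiable
bend to recover. Noise is Gaussian truncated at zero (clipping), keeping the
planted linear structure while guaranteeing nonnegativity; the noise scale
(default 0.05) is a free parameter, not an estimate of any real dataset.

**Outcomes** follow an exponential proportional-hazards model on the z-scored
level of one designated component: subject hazard λ₀·exp(β·z) with
administrative censoring (default 24 months, matching a typical follow-up
median). β defaults to 0.8 per SD, which yields a training C-index ≈ 0.7 — the
moderate prognostic strength reported for imaging biomarkers in this setting.
λ₀ is calibrated by bisection against the realized component scores so the
expected failure fraction at the 12-month horizon equals the configured target
(0.11 for the training-like cohort of N=104; 0.46 at N=24 for the
validation-like preset). Passing `planted_W` draws a new cohort from the same
feature-generating process, which is what frozen validation presumes.

Passing tests on these cohorts shows the pipeline recovers structure it is
designed for under its own assumptions (linear nonnegative mixing, proportional
hazards, subtype-dominated samples). It does not show that real CT radiomics of
bladder lesions satisfy those assumptions, nor does it reproduce any clinical
cohort's performance figures.

## Problem sizes and determinism

The test and acceptance suites run the study-scale matrix (54×104) with 5–10
restarts per rank rather than 100, which the planted signal-to-noise makes
sufficient; operation defaults keep the larger values. Every stochastic stage
draws from `numpy.random.Generator` seeded deterministically from a single
master seed (per-stage seeds by stable hashing), so reruns with the same
configuration are bit-identical; no global random state is used or mutated.

## Known limitations

- No filtered-image (wavelet/LoG) features; original-image set only.
- Mesh-based shape features inherit a small anti-aliasing bias on lesions only a
  few voxels across.
- The Cox step is single-covariate by design; no clinical-covariate adjustment,
  proportionality diagnostics, or competing risks.
- NNLS projection assumes the validation cohort shares the training cohort's
  feature scaling; out-of-range values are clipped into [0, 1].
- The collinearity threshold reproduces the published *rule* ("high
  collinearity"), not the published count of dropped features, which depends on
  the original data.
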