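"""Factorize a synthetic radiomics cohort and choose the number of components.

The generator plants a rank-5 nonnegative structure (five radiomics
subtypes) in a 54-feature x 104-sample matrix.  The residual sum of squares
of the best-of-restarts factorization is scanned over k = 2..10; the rank at
the bend of the curve (largest discrete second difference) is selected.
"""

import numpy as np

from radionmf import nmf
from radionmf.preprocess import FeatureMatrix, collinearity_filter, nonnegative_scale
from radionmf.synthetic import CohortSpec, make_cohort

features, clinical, W_true, H_true = make_cohort(CohortSpec(seed=11))
fm = FeatureMatrix.from_frame(features)
filtered, dropped = collinearity_filter(fm, r_threshold=0.90)
scaled = nonnegative_scale(filtered)
print(f"cohort: {fm.shape[0]} features x {fm.shape[1]} samples; "
      f"{len(dropped)} collinear features dropped")

curve = nmf.rss_curve(scaled.values, k_min=2, k_max=10, n_restarts=10, seed=42)
for k, rss in zip(curve.ks, curve.rss):
    print(f"  k={k}: best RSS {rss:8.3f}")
k_star = nmf.select_rank(curve)
print(f"selected rank k* = {k_star} (planted rank was 5)")
print("The RSS drops steeply while real components remain and flattens once")
print("only noise is left; the bend marks the planted dimensionality.")
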