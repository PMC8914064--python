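"""Feature-matrix assembly, collinearity filtering, and nonnegative scaling.

The factorization downstream requires a nonnegative matrix V (M features x
N samples).  This module builds V from per-sample feature vectors, removes
collinear features with a greedy pairwise-|r| rule, and min-max scales each
surviving feature to [0, 1].  Scaling parameters and the retained feature
list are kept so an independent validation cohort can be projected through
the identical, frozen transformation.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "assemble",
    "collinearity_filter",
    "nonnegative_scale",
    "apply_scaling",
]


@dataclasses.dataclass
class FeatureMatrix:
    """Nonnegative feature-by-sample matrix with identifiers.

    ``values`` has shape (M, N): one row per feature, one column per sample.
    After :func:`nonnegative_scale`, ``scale_min``/``scale_max`` hold the
    per-feature training minima and maxima used for the [0, 1] mapping.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    scale_min: np.ndarray | None = None
    scale_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = list(self.feature_names)
        self.sample_ids = list(self.sample_ids)
        m, n = self.values.shape
        if len(self.feature_names) != m:
            raise ValueError(f"{len(self.feature_names)} names for {m} feature rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} ids for {n} sample columns")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature names are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def save_params(self, path: str | Path, dropped: list[str] | None = None) -> None:
        """JSON sidecar: retained features, scaling parameters, dropped names."""
        payload = {
            "feature_names": self.feature_names,
            "scale_min": None if self.scale_min is None else self.scale_min.tolist(),
            "scale_max": None if self.scale_max is None else self.scale_max.tolist(),
            "dropped": dropped or [],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def assemble(feature_vectors: list[pd.Series], sample_ids: list[str]) -> FeatureMatrix:
    """Stack per-sample feature vectors into a FeatureMatrix.

    All vectors must share the same feature names; columns follow the order
    of ``sample_ids``.
    """
    if len(feature_vectors) != len(sample_ids):
        raise ValueError("one feature vector per sample id required")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    names = list(feature_vectors[0].index)
    for sid, fv in zip(sample_ids, feature_vectors):
        if list(fv.index) != names:
            raise ValueError(f"sample {sid!r} has a mismatched feature set/order")
    values = np.column_stack([fv.to_numpy(dtype=float) for fv in feature_vectors])
    return FeatureMatrix(values, names, list(sample_ids))


def collinearity_filter(
    fm: FeatureMatrix, r_threshold: float = 0.90
) -> tuple[FeatureMatrix, list[str]]:
    """Greedy elimination of highly correlated feature pairs.

    Constant features are dropped first.  Then, while any pair of features
    has Pearson |r| above ``r_threshold``, the member of the worst
    (largest-|r|) pair with the larger mean absolute correlation to all
    remaining features is dropped; ties go to the feature appearing later
    in the declared order.
    """
    if fm.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    X = fm.values
    names = fm.feature_names

    keep = [i for i in range(X.shape[0]) if np.ptp(X[i]) > 0]
    dropped = [names[i] for i in range(X.shape[0]) if np.ptp(X[i]) == 0]

    if len(keep) >= 2:
        sub = X[keep]
        with np.errstate(invalid="ignore"):
            r = np.abs(np.corrcoef(sub))
        np.fill_diagonal(r, 0.0)
        active = list(range(len(keep)))
        while True:
            ra = r[np.ix_(active, active)]
            worst = ra.max()
            if worst <= r_threshold:
                break
            ai, aj = np.unravel_index(np.argmax(ra), ra.shape)
            i, j = active[ai], active[aj]
            # mean |r| of each candidate to all other remaining features
            others = [a for a in active if a not in (i, j)]
            mean_i = r[i, others].mean() if others else 0.0
            mean_j = r[j, others].mean() if others else 0.0
            if mean_i > mean_j:
                out = i
            elif mean_j > mean_i:
                out = j
            else:  # tie: drop the later name in the declared order
                out = max(i, j)
            dropped.append(names[keep[out]])
            active.remove(out)
        keep = [keep[a] for a in sorted(active)]

    if len(keep) < 2:
        raise ValueError("fewer than 2 features survive the collinearity filter")
    surviving = [names[i] for i in keep]
    out_fm = FeatureMatrix(X[keep], surviving, fm.sample_ids)
    # report drops in the declared feature order
    dropped_sorted = [n for n in names if n in set(dropped)]
    return out_fm, dropped_sorted


def nonnegative_scale(fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale every feature row to [0, 1]; store the parameters.

    Constant rows cannot be scaled and must be removed beforehand (the
    collinearity filter does this).
    """
    lo = fm.values.min(axis=1)
    hi = fm.values.max(axis=1)
    if np.any(hi - lo == 0):
        bad = [fm.feature_names[i] for i in np.flatnonzero(hi - lo == 0)]
        raise ValueError(f"constant features cannot be min-max scaled: {bad}")
    scaled = (fm.values - lo[:, None]) / (hi - lo)[:, None]
    return FeatureMatrix(
        scaled, fm.feature_names, fm.sample_ids, scale_min=lo, scale_max=hi
    )


def apply_scaling(trained: FeatureMatrix, new: FeatureMatrix) -> FeatureMatrix:
    """Project a new cohort through frozen training min-max parameters.

    Rows are aligned by feature name; values outside the training range are
    clipped into [0, 1].
    """
    if trained.scale_min is None or trained.scale_max is None:
        raise ValueError("trained matrix has no stored scaling parameters")
    missing = [n for n in trained.feature_names if n not in set(new.feature_names)]
    if missing:
        raise ValueError(f"new cohort is missing trained features: {missing}")
    order = [new.feature_names.index(n) for n in trained.feature_names]
    X = new.values[order]
    lo, hi = trained.scale_min, trained.scale_max
    scaled = np.clip((X - lo[:, None]) / (hi - lo)[:, None], 0.0, 1.0)
    return FeatureMatrix(
        scaled, list(trained.feature_names), new.sample_ids, scale_min=lo, scale_max=hi
    )
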