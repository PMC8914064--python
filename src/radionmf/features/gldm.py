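"""Grey Level Dependence Matrix features (14).

For each ROI voxel, its dependence is 1 (the voxel itself) plus the number
of 26-neighbours inside the ROI whose grey level differs from the centre by
at most ``alpha`` (default 0).  P[level, dependence] counts voxels, so the
matrix total equals the ROI voxel count.
"""

from __future__ import annotations

import numpy as np

from ..volume import Discretization
from ._offsets import OFFSETS_26, paired_slices

_EPS = np.spacing(1.0)

GLDM_FEATURES = [
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]


def gldm_matrix(disc: Discretization, alpha: int = 0) -> np.ndarray:
    lv = disc.levels
    mask = disc.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = paired_slices(lv.shape, off)
        ok = mask[src] & mask[dst] & (np.abs(lv[src] - lv[dst]) <= alpha)
        dep[dst] += ok
    dep = dep + 1  # the centre voxel always depends on itself
    levels = lv[mask] - 1
    deps = dep[mask] - 1
    P = np.zeros((disc.n_levels, deps.max() + 1), dtype=np.int64)
    np.add.at(P, (levels, deps), 1)
    return P


def extract_gldm(disc: Discretization, alpha: int = 0) -> dict[str, float]:
    P = gldm_matrix(disc, alpha)
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    return {
        "SmallDependenceEmphasis": float((P / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p[p > 0] * np.log2(p[p > 0])).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nz),
    }
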