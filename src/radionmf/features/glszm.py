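"""Grey Level Size Zone Matrix features (16).

A zone is a 26-connected component of equal grey level; the matrix
P[level, size] counts zones.  Direction-independent, so a single matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume import Discretization

_EPS = np.spacing(1.0)

GLSZM_FEATURES = [
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: Discretization) -> np.ndarray:
    lv = np.where(disc.mask, disc.levels, 0)
    ng = disc.n_levels
    zones: list[tuple[int, int]] = []  # (level-1, size)
    for g in np.unique(lv[lv > 0]):
        lab, n = ndimage.label(lv == g, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g) - 1, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size), dtype=np.int64)
    for g, s in zones:
        P[g, s - 1] += 1
    return P


def extract_glszm(disc: Discretization) -> dict[str, float]:
    P = glszm_matrix(disc)
    nz = P.sum()
    n_voxels = int(disc.mask.sum())
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    return {
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / nz**2),
        "SizeZoneNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
    }
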