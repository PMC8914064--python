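"""Grey Level Run Length Matrix features (16).

A run is a maximal string of consecutive voxels with the same grey level
along one of the 13 unique 3D directions at distance 1.  One run-length
matrix R[level, length] is built per direction; features are computed per
direction and averaged.
"""

from __future__ import annotations

import numpy as np

from ..volume import Discretization
from ._offsets import OFFSETS_13, paired_slices

_EPS = np.spacing(1.0)

GLRLM_FEATURES = [
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]


def _runs_one_direction(lv: np.ndarray, offset) -> np.ndarray:
    """Run-length count matrix R[level-1, length-1] for one direction.

    Dynamic programme: f[v] = length of the run continuing from v in +offset
    direction; a voxel starts a run when its -offset neighbour has a
    different level (or lies outside the ROI/grid).
    """
    shape = lv.shape
    ng = int(lv.max())
    max_len = int(np.ceil(np.sqrt(sum((d * (n - 1)) ** 2 for d, n in zip(offset, shape)))))
    max_len = max(max_len, 1) + 1

    src, dst = paired_slices(shape, offset)
    f = np.where(lv > 0, 1, 0).astype(np.int64)
    # iterate until no chain can be longer; each pass extends known suffix runs
    same = np.zeros(shape, dtype=bool)
    same[src] = (lv[src] == lv[dst]) & (lv[src] > 0)
    # f[v] = 1 + f[v+d] where same; evaluate by repeated relaxation along the axis
    steps = max(abs(d) * (n - 1) for d, n in zip(offset, shape))
    for _ in range(steps):
        f_shift = np.zeros(shape, dtype=np.int64)
        f_shift[src] = f[dst]
        new = np.where(same, 1 + f_shift, np.where(lv > 0, 1, 0))
        if np.array_equal(new, f):
            break
        f = new

    # run starts: ROI voxel whose -offset predecessor differs in level
    prev_same = np.zeros(shape, dtype=bool)
    prev_same[dst] = (lv[dst] == lv[src]) & (lv[dst] > 0)
    starts = (lv > 0) & ~prev_same
    levels = lv[starts] - 1
    lengths = f[starts] - 1
    R = np.zeros((ng, lengths.max() + 1 if lengths.size else 1), dtype=np.int64)
    np.add.at(R, (levels, lengths), 1)
    return R


def glrlm_matrices(disc: Discretization) -> list[np.ndarray]:
    lv = np.where(disc.mask, disc.levels, 0)
    return [_runs_one_direction(lv, off) for off in OFFSETS_13]


def _features_one(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    i = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    ell = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    p = R / nr
    mu_i = (p * i).sum()
    mu_l = (p * ell).sum()
    return {
        "ShortRunEmphasis": float((R / ell**2).sum() / nr),
        "LongRunEmphasis": float((R * ell**2).sum() / nr),
        "GrayLevelNonUniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((R.sum(axis=1) ** 2).sum() / nr**2),
        "RunLengthNonUniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((R.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (ell - mu_l) ** 2).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((R / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((R * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((R / (i**2 * ell**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((R * i**2 / ell**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((R * ell**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((R * i**2 * ell**2).sum() / nr),
    }


def extract_glrlm(disc: Discretization) -> dict[str, float]:
    n_voxels = int(disc.mask.sum())
    per = [
        _features_one(R, n_voxels) for R in glrlm_matrices(disc) if R.sum() > 0
    ]
    return {name: float(np.mean([f[name] for f in per])) for name in GLRLM_FEATURES}
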