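"""Grey Level Co-occurrence Matrix features (24).

One symmetric co-occurrence matrix is accumulated per direction offset
(13 unique offsets at distance 1 in 3D); each feature is computed per
offset and then averaged over the offsets that contain at least one
co-occurring voxel pair.
"""

from __future__ import annotations

import numpy as np

from ..volume import Discretization
from ._offsets import OFFSETS_13, paired_slices

_EPS = np.spacing(1.0)

GLCM_FEATURES = [
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
]


def glcm_matrices(disc: Discretization) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per 3D offset."""
    ng = disc.n_levels
    lv = disc.levels
    mask = disc.mask
    mats = []
    for off in OFFSETS_13:
        src, dst = paired_slices(lv.shape, off)
        ok = mask[src] & mask[dst]
        a = lv[src][ok] - 1
        b = lv[dst][ok] - 1
        counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng)
        mats.append(counts + counts.T)
    return mats


def _features_one(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    p = P / P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # diagonal (difference) and anti-diagonal (sum) marginal distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    diff_avg = float((k_diff * p_diff).sum())

    hxy = float(-(p * np.log2(p + _EPS)).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(p * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())

    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        corr = (float((p * ii * jj).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0  # single grey level: perfectly correlated by convention

    off_diag = np.abs(ii - jj) > 0
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    # MCC: second largest eigenvalue of the grey-level transition matrix Q
    occupied = px > 0
    if occupied.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(occupied, occupied)]
        pxs = px[occupied]
        pys = py[occupied]
        Q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, ev[-2])))

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-(p_diff * np.log2(p_diff + _EPS)).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": float((p * ii).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-(p_sum * np.log2(p_sum + _EPS)).sum()),
        "SumSquares": float((p * (ii - mu_x) ** 2).sum()),
    }


def extract_glcm(disc: Discretization) -> dict[str, float]:
    """GLCM features averaged over the 13 direction offsets with any pairs."""
    mats = [m for m in glcm_matrices(disc) if m.sum() > 0]
    if not mats:
        # single isolated voxel: no co-occurrences in any direction
        return {name: 0.0 for name in GLCM_FEATURES}
    per_offset = [_features_one(m) for m in mats]
    return {
        name: float(np.mean([f[name] for f in per_offset])) for name in GLCM_FEATURES
    }
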