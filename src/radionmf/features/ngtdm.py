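"""Neighbouring Grey Tone Difference Matrix features (5).

For grey level i: n_i voxels, probability p_i = n_i / Nvp, and
s_i = sum over those voxels of |i - mean grey level of the voxel's ROI
neighbours| (26-neighbourhood, centre excluded).  Voxels with no ROI
neighbour are excluded from Nvp.
"""

from __future__ import annotations

import numpy as np

from ..volume import Discretization
from ._offsets import neighbour_sums

NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

_COARSENESS_CAP = 1e6


def ngtdm_table(disc: Discretization) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (grey levels i, counts n_i, sums s_i) over valid ROI voxels."""
    lv = disc.levels.astype(np.float64)
    mask = disc.mask
    sums, counts = neighbour_sums(lv, mask)
    valid = mask & (counts > 0)
    avg = np.zeros(lv.shape)
    avg[valid] = sums[valid] / counts[valid]
    diff = np.abs(lv - avg)

    ng = disc.n_levels
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    lv_v = disc.levels[valid] - 1
    np.add.at(n_i, lv_v, 1)
    np.add.at(s_i, lv_v, diff[valid])
    return np.arange(1, ng + 1, dtype=np.float64), n_i, s_i


def extract_ngtdm(disc: Discretization) -> dict[str, float]:
    i, n_i, s_i = ngtdm_table(disc)
    nvp = n_i.sum()
    if nvp == 0:
        return {name: 0.0 for name in NGTDM_FEATURES}
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    ip, pp, sp = i[present], p_i[present], s_i[present]

    denom = float((p_i * s_i).sum())
    coarseness = 1.0 / denom if denom > 0 else _COARSENESS_CAP

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        ipi = ip * pp
        busy_den = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            ).sum()
            / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
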