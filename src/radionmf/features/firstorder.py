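"""18 first-order (intensity histogram) features.

All statistics are computed over the raw HU values inside the mask; Entropy
and Uniformity use the discretized grey-level histogram so they share the
bin width of the texture families.  Moments are population moments (no
small-sample correction); Kurtosis is the plain fourth standardized moment,
not excess kurtosis.
"""

from __future__ import annotations

import numpy as np

from ..volume import Discretization, VolumeWithMask

FIRSTORDER_FEATURES = [
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
]


def extract_firstorder(vm: VolumeWithMask, disc: Discretization) -> dict[str, float]:
    x = vm.roi_values
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population variance
    sd = np.sqrt(var)

    p = disc.histogram / disc.histogram.sum()
    p_nz = p[p > 0]
    entropy = float(-(p_nz * np.log2(p_nz)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    if sd > 0:
        z = (x - mean) / sd
        skew = float((z**3).mean())
        kurt = float((z**4).mean())
    else:
        skew = 0.0
        kurt = 0.0

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * vm.voxel_volume,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
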