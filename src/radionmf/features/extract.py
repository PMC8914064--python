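"""Full 107-feature original-image radiomics extraction.

Pipeline: resample to the working spacing (default 1 x 1 x 2 mm, trilinear
image / nearest-neighbour mask) -> fixed-bin-width grey-level discretization
(default 25 HU) -> seven feature families:

    shape 14, first-order 18, GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5

Feature names are family-qualified (``glcm/Contrast``) and their order is a
fixed contract: the same 107 names in the same order on every run.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd

from ..volume import VolumeWithMask, discretize, resample
from .firstorder import FIRSTORDER_FEATURES, extract_firstorder
from .gldm import GLDM_FEATURES, extract_gldm
from .glcm import GLCM_FEATURES, extract_glcm
from .glrlm import GLRLM_FEATURES, extract_glrlm
from .glszm import GLSZM_FEATURES, extract_glszm
from .ngtdm import NGTDM_FEATURES, extract_ngtdm
from .shape import SHAPE_FEATURES, extract_shape

FAMILY_FEATURES: dict[str, list[str]] = {
    "shape": SHAPE_FEATURES,
    "firstorder": FIRSTORDER_FEATURES,
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "gldm": GLDM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
}

#: the 107 feature names, in extraction order
FEATURE_NAMES: list[str] = [
    f"{family}/{name}" for family, names in FAMILY_FEATURES.items() for name in names
]


@dataclasses.dataclass
class ExtractionConfig:
    """Settings of the extraction pipeline.

    target_spacing : mm per axis the volume is resampled to before extraction
    bin_width      : grey-level bin width in HU for discretization
    do_resample    : skip resampling when False (input already on-grid)
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    bin_width: float = 25.0
    do_resample: bool = True


def extract_all(vm: VolumeWithMask, config: ExtractionConfig | None = None) -> pd.Series:
    """Extract the full 107-feature vector from a volume + mask.

    Returns a Series indexed by the family-qualified feature names in the
    canonical order.  Degenerate ROIs (single voxel, single grey level)
    produce the closed-form degenerate feature values with a warning, never
    NaN.
    """
    config = config or ExtractionConfig()
    if config.do_resample:
        vm = resample(vm, config.target_spacing)
    disc = discretize(vm, config.bin_width)
    if vm.mask.sum() < 2 or disc.n_levels < 2:
        warnings.warn(
            "degenerate ROI (single voxel or single grey level); texture "
            "features take their closed-form degenerate values",
            stacklevel=2,
        )

    values: dict[str, float] = {}
    for family, fn in (
        ("shape", lambda: extract_shape(vm)),
        ("firstorder", lambda: extract_firstorder(vm, disc)),
        ("glcm", lambda: extract_glcm(disc)),
        ("glrlm", lambda: extract_glrlm(disc)),
        ("glszm", lambda: extract_glszm(disc)),
        ("gldm", lambda: extract_gldm(disc)),
        ("ngtdm", lambda: extract_ngtdm(disc)),
    ):
        fam = fn()
        values.update({f"{family}/{k}": v for k, v in fam.items()})

    out = pd.Series(values, dtype=float).reindex(FEATURE_NAMES)
    assert len(out) == 107 and not out.index.has_duplicates
    return out


def extract_to_csv(
    pairs: list[tuple[str, Path | str, Path | str]],
    out_csv: Path | str,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Extract features for (sample_id, image_path, mask_path) NIfTI pairs.

    Writes one row per sample: ``sample_id`` plus the 107 named columns.
    """
    from ..volume import load_nifti_pair

    rows = {}
    for sample_id, image_path, mask_path in pairs:
        vm = load_nifti_pair(image_path, mask_path)
        rows[sample_id] = extract_all(vm, config)
    df = pd.DataFrame(rows).T
    df.index.name = "sample_id"
    df.to_csv(out_csv)
    return df
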