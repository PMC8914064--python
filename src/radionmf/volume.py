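"""3D volume + lesion mask container, grid resampling and grey-level discretization.

The container pairs a CT intensity grid (Hounsfield units) with an aligned
binary lesion mask and the physical voxel spacing in millimetres.  Array axes
follow the spacing order: axis ``i`` of the array has pitch ``spacing[i]`` mm.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeWithMask",
    "Discretization",
    "resample",
    "discretize",
    "load_nifti_pair",
    "save_nifti_pair",
]


@dataclasses.dataclass
class VolumeWithMask:
    """A 3D intensity grid (HU) with an aligned binary lesion mask.

    Parameters
    ----------
    image:
        3D array of intensities in Hounsfield units.
    mask:
        Boolean array of the same shape; True marks lesion voxels.
    spacing:
        Physical voxel spacing in mm along each array axis; strictly positive.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.image.ndim != 3:
            raise ValueError(f"image must be 3D, got shape {self.image.shape}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not self.mask.any():
            raise ValueError("mask is empty: no lesion voxels")

    @property
    def roi_values(self) -> np.ndarray:
        """Intensities of the lesion voxels, flattened."""
        return self.image[self.mask]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class Discretization:
    """Grey-level map of a masked volume at a fixed bin width.

    ``levels`` holds integer levels 1..n_levels inside the mask and 0 outside.
    Level of a voxel x is ``floor((I(x) - min_ROI) / bin_width) + 1``, so the
    map is invariant to adding a constant to the image.  Bins between occupied
    levels are retained (they may be empty).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float
    histogram: np.ndarray  # counts for levels 1..n_levels

    @property
    def grey_levels(self) -> np.ndarray:
        return np.arange(1, self.n_levels + 1)


def resample(
    vm: VolumeWithMask, target_spacing: tuple[float, float, float]
) -> VolumeWithMask:
    """Resample image and mask onto a grid with the given spacing (mm).

    The image is interpolated trilinearly and the mask by nearest neighbour,
    so mask values stay strictly binary.  If the input is already on the
    target spacing it is returned unchanged.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be 3 positive values, got {target_spacing}")
    if np.allclose(vm.spacing, target_spacing):
        return vm

    # SimpleITK's array view is index-reversed (z, y, x) relative to numpy;
    # spacing tuples handed to sitk must therefore be reversed too.
    img = sitk.GetImageFromArray(vm.image)
    img.SetSpacing(tuple(reversed(vm.spacing)))
    msk = sitk.GetImageFromArray(vm.mask.astype(np.uint8))
    msk.SetSpacing(tuple(reversed(vm.spacing)))

    new_size = [
        max(1, int(round(n * s / t)))
        for n, s, t in zip(vm.image.shape, vm.spacing, target_spacing)
    ]
    rs = sitk.ResampleImageFilter()
    rs.SetOutputSpacing(tuple(reversed(target_spacing)))
    rs.SetSize(tuple(reversed(new_size)))
    rs.SetOutputOrigin(img.GetOrigin())
    rs.SetOutputDirection(img.GetDirection())
    # grid points beyond the last input voxel centre take the nearest voxel's
    # value instead of an arbitrary fill, so constants stay constant
    rs.SetUseNearestNeighborExtrapolator(True)
    rs.SetInterpolator(sitk.sitkLinear)
    new_image = sitk.GetArrayFromImage(rs.Execute(img))
    rs.SetInterpolator(sitk.sitkNearestNeighbor)
    new_mask = sitk.GetArrayFromImage(rs.Execute(msk)).astype(bool)

    if not new_mask.any():
        raise ValueError(
            "mask is empty after resampling to spacing "
            f"{target_spacing}; lesion too small for the target grid"
        )
    return VolumeWithMask(new_image, new_mask, target_spacing)


def discretize(vm: VolumeWithMask, bin_width: float = 25.0) -> Discretization:
    """Discretize ROI intensities into fixed-width grey-level bins.

    level(x) = floor((I(x) - min_ROI) / bin_width) + 1; levels run from 1.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    roi = vm.roi_values
    lo = roi.min()
    levels = np.zeros(vm.image.shape, dtype=np.int64)
    levels[vm.mask] = np.floor((vm.image[vm.mask] - lo) / bin_width).astype(np.int64) + 1
    n_levels = int(levels.max())
    histogram = np.bincount(levels[vm.mask], minlength=n_levels + 1)[1:]
    return Discretization(
        levels=levels,
        mask=vm.mask,
        n_levels=n_levels,
        bin_width=float(bin_width),
        histogram=histogram,
    )


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_nifti_pair(vm: VolumeWithMask, image_path: str | Path, mask_path: str | Path) -> None:
    """Write image and mask as a pair of NIfTI files with matching affines."""
    aff = _affine(vm.spacing)
    nib.save(nib.Nifti1Image(vm.image.astype(np.float32), aff), str(image_path))
    nib.save(nib.Nifti1Image(vm.mask.astype(np.uint8), aff), str(mask_path))


def load_nifti_pair(image_path: str | Path, mask_path: str | Path) -> VolumeWithMask:
    """Load an image/mask NIfTI pair; spacing is read from the image header."""
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    image = np.asanyarray(img.dataobj, dtype=np.float64)
    mask = np.asanyarray(msk.dataobj) > 0.5
    return VolumeWithMask(image, mask, spacing)
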