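"""14 morphological (shape) features of a 3D lesion mask.

Mesh-based quantities (volume, surface area, sphericity, diameters) come from
a triangulated isosurface of the binary mask at level 0.5; axis lengths come
from a principal component analysis of the physical voxel-centre coordinates.
Shape features depend only on the mask and spacing, never on intensities.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..volume import VolumeWithMask

SHAPE_FEATURES = [
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
]


def _mesh(mask: np.ndarray, spacing: tuple[float, float, float]):
    """Triangulated isosurface of the mask at level 0.5.

    The binary indicator is anti-aliased (Gaussian, sigma = 1 voxel) before
    meshing: marching cubes on a raw 0/1 grid produces a staircase surface
    whose area overestimates smooth lesions by 5-10%, which biases
    sphericity well below its analytic value.  Thin structures where the
    smoothed field never reaches 0.5 fall back to the raw indicator.
    """
    from scipy import ndimage

    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, 1.0)
    if smoothed.max() <= 0.5:
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=spacing)
    return verts, faces

def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    # divergence theorem over signed tetrahedra anchored at the origin
    tri = verts[faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


def _max_pairwise(points: np.ndarray) -> float:
    """Largest pairwise Euclidean distance; convex hull prunes when possible."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(pts) > 32 and pts.shape[1] <= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar/collinear) input
            pass
    return float(pdist(pts).max())


def _surface_voxel_coords(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical centre coordinates of voxels on the mask boundary."""
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask)
    surf = mask & ~eroded
    idx = np.argwhere(surf)
    return idx * np.asarray(spacing)


def extract_shape(vm: VolumeWithMask) -> dict[str, float]:
    """Compute the 14 shape features of the lesion mask."""
    mask = vm.mask
    spacing = vm.spacing
    n_vox = int(mask.sum())
    voxel_volume = n_vox * vm.voxel_volume

    if n_vox == 1:
        # a single voxel is treated as its bounding box
        a, b, c = spacing
        mesh_volume = a * b * c
        area = 2 * (a * b + a * c + b * c)
    else:
        verts, faces = _mesh(mask, spacing)
        mesh_volume = _mesh_volume(verts, faces)
        area = float(measure.mesh_surface_area(verts, faces))

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area

    surf = _surface_voxel_coords(mask, spacing)
    max3d = _max_pairwise(surf)
    # 2D diameters: max over planes perpendicular to one array axis
    diam2d = {}
    for fixed_axis, name in ((2, "Slice"), (0, "Column"), (1, "Row")):
        keep = [a for a in range(3) if a != fixed_axis]
        best = 0.0
        idx_fixed = np.round(surf[:, fixed_axis] / spacing[fixed_axis]).astype(int)
        for plane in np.unique(idx_fixed):
            pts = surf[idx_fixed == plane][:, keep]
            best = max(best, _max_pairwise(pts))
        diam2d[name] = best

    coords = np.argwhere(mask) * np.asarray(spacing)
    if n_vox < 2:
        eig = np.zeros(3)
    else:
        eig = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": diam2d["Slice"],
        "Maximum2DDiameterColumn": diam2d["Column"],
        "Maximum2DDiameterRow": diam2d["Row"],
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
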