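"""Shared helpers for 3D texture families: direction offsets and shifting."""

from __future__ import annotations

import itertools

import numpy as np

#: the 13 unique direction offsets at Chebyshev distance 1 in 3D
#: (one representative per +/- pair of the 26-neighbourhood)
OFFSETS_13: list[tuple[int, int, int]] = [
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)
]

#: all 26 neighbour offsets
OFFSETS_26: list[tuple[int, int, int]] = [
    d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
]


def paired_slices(shape, offset):
    """Index slices (src, dst) so that arr[dst] is arr[src] shifted by offset."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        src.append(slice(max(0, -d), n - max(0, d)))
        dst.append(slice(max(0, d), n - max(0, -d)))
    return tuple(src), tuple(dst)


def neighbour_sums(values: np.ndarray, inside: np.ndarray):
    """Per-voxel sum and count of 26-neighbour ``values`` restricted to ``inside``.

    Returns (sums, counts) arrays of the full grid shape; voxels outside
    ``inside`` are included in the output but their neighbours are not
    counted for anyone unless inside.
    """
    sums = np.zeros(values.shape, dtype=np.float64)
    counts = np.zeros(values.shape, dtype=np.int64)
    vals_in = np.where(inside, values, 0.0)
    for off in OFFSETS_26:
        src, dst = paired_slices(values.shape, off)
        sums[dst] += vals_in[src]
        counts[dst] += inside[src]
    return sums, counts
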