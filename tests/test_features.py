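"""Radiomics feature families against independent brute-force oracles.

Each texture family's matrix builder is checked on small random grids
against a direct voxel-loop reimplementation written here (dictionaries and
explicit neighbour loops, no shared code with the package), plus skimage's
co-occurrence routine as an external GLCM oracle.  Shape and first-order
features are checked against analytic values and closed forms.
"""

import itertools

import numpy as np
import pytest

from radionmf.features import (
    ExtractionConfig,
    FAMILY_FEATURES,
    FEATURE_NAMES,
    extract_all,
    extract_firstorder,
    extract_glcm,
    extract_shape,
    gldm_matrix,
    glcm_matrices,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)
from radionmf.features._offsets import OFFSETS_13, OFFSETS_26
from radionmf.synthetic import PhantomSpec, make_phantom
from radionmf.volume import VolumeWithMask, discretize


def _random_volume(rng, shape=(6, 6, 4), n_levels=4, mask_p=0.7):
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < mask_p
    if mask.sum() < 2:
        mask[0, 0, 0] = mask[0, 0, 1] = True
    image = (levels - 1) * 25.0 + 1.0  # maps back to the same levels at bin 25
    return VolumeWithMask(image, mask, (1, 1, 1))


# ---------------------------------------------------------------- oracles


def _brute_glcm(levels, mask, ng, offset):
    P = np.zeros((ng, ng))
    for idx in np.argwhere(mask):
        nb = idx + np.asarray(offset)
        if (nb < 0).any() or (nb >= np.asarray(mask.shape)).any():
            continue
        nb = tuple(nb)
        if mask[nb]:
            a, b = levels[tuple(idx)] - 1, levels[nb] - 1
            P[a, b] += 1
            P[b, a] += 1
    return P


def _brute_runs(levels, mask, ng, offset):
    """Run-length counts by explicit line walking."""
    lv = np.where(mask, levels, 0)
    shape = lv.shape
    runs = {}
    d = np.asarray(offset)
    for start in np.ndindex(shape):
        prev = np.asarray(start) - d
        if (prev >= 0).all() and (prev < shape).all() and lv[tuple(prev)] == lv[start] and lv[start] > 0:
            continue  # not a run start
        if lv[start] == 0:
            continue
        g = lv[start]
        length = 1
        cur = np.asarray(start) + d
        while (cur >= 0).all() and (cur < shape).all() and lv[tuple(cur)] == g:
            length += 1
            cur = cur + d
        runs[(g, length)] = runs.get((g, length), 0) + 1
    R = np.zeros((ng, max((l for (_, l) in runs), default=1)))
    for (g, l), c in runs.items():
        R[g - 1, l - 1] = c
    return R


def _brute_zones(levels, mask, ng):
    """Zone sizes by flood fill with 26-connectivity."""
    lv = np.where(mask, levels, 0)
    seen = np.zeros(lv.shape, dtype=bool)
    zones = []
    for start in np.ndindex(lv.shape):
        if lv[start] == 0 or seen[start]:
            continue
        g = lv[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            v = stack.pop()
            size += 1
            for off in OFFSETS_26:
                nb = tuple(np.asarray(v) + off)
                if any(c < 0 or c >= s for c, s in zip(nb, lv.shape)):
                    continue
                if not seen[nb] and lv[nb] == g:
                    seen[nb] = True
                    stack.append(nb)
        zones.append((g, size))
    P = np.zeros((ng, max((s for _, s in zones), default=1)))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def _brute_gldm(levels, mask, ng, alpha=0):
    deps = {}
    for idx in np.argwhere(mask):
        g = levels[tuple(idx)]
        count = 1  # centre
        for off in OFFSETS_26:
            nb = idx + np.asarray(off)
            if (nb < 0).any() or (nb >= np.asarray(mask.shape)).any():
                continue
            nb = tuple(nb)
            if mask[nb] and abs(int(levels[nb]) - int(g)) <= alpha:
                count += 1
        deps[(g, count)] = deps.get((g, count), 0) + 1
    P = np.zeros((ng, max(c for (_, c) in deps)))
    for (g, c), n in deps.items():
        P[g - 1, c - 1] = n
    return P


def _brute_ngtdm(levels, mask, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for idx in np.argwhere(mask):
        vals = []
        for off in OFFSETS_26:
            nb = idx + np.asarray(off)
            if (nb < 0).any() or (nb >= np.asarray(mask.shape)).any():
                continue
            nb = tuple(nb)
            if mask[nb]:
                vals.append(levels[nb])
        if not vals:
            continue
        g = levels[tuple(idx)]
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - np.mean(vals))
    return n_i, s_i


# ----------------------------------------------------------- matrix checks


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_glcm_matrices_match_brute_force(seed):
    vm = _random_volume(np.random.default_rng(seed))
    disc = discretize(vm, 25.0)
    mats = glcm_matrices(disc)
    for off, P in zip(OFFSETS_13, mats):
        expected = _brute_glcm(disc.levels, disc.mask, disc.n_levels, off)
        assert np.array_equal(P, expected), f"offset {off}"


def test_glcm_matches_skimage_on_single_slice():
    """In-plane co-occurrences equal skimage.feature.graycomatrix counts."""
    from skimage.feature import graycomatrix

    rng = np.random.default_rng(5)
    img2d = rng.integers(0, 5, size=(12, 12))
    vm = VolumeWithMask(
        (img2d * 25.0 + 1.0)[..., None], np.ones((12, 12, 1), bool), (1, 1, 1)
    )
    disc = discretize(vm, 25.0)
    mats = dict(zip(OFFSETS_13, glcm_matrices(disc)))
    # skimage angle -> (drow, dcol) offsets for distance 1
    for angle, off3d in [(0.0, (0, 1, 0)), (np.pi / 2, (1, 0, 0))]:
        sk = graycomatrix(
            img2d, [1], [angle], levels=5, symmetric=True
        )[:, :, 0, 0]
        ours = mats[off3d] if off3d in mats else mats[tuple(-np.array(off3d))]
        assert np.array_equal(ours, sk)


@pytest.mark.parametrize("seed", [0, 3])
def test_glrlm_matrices_match_brute_force(seed):
    vm = _random_volume(np.random.default_rng(seed))
    disc = discretize(vm, 25.0)
    for off, R in zip(OFFSETS_13, glrlm_matrices(disc)):
        expected = _brute_runs(disc.levels, disc.mask, disc.n_levels, off)
        w = max(R.shape[1], expected.shape[1])
        Rp = np.pad(R, ((0, 0), (0, w - R.shape[1])))
        Ep = np.pad(expected, ((0, 0), (0, w - expected.shape[1])))
        assert np.array_equal(Rp, Ep), f"offset {off}"


def test_glrlm_total_run_length_equals_voxel_count():
    """Runs partition each direction's lines: sum(R * length) = ROI voxels."""
    vm = _random_volume(np.random.default_rng(9))
    disc = discretize(vm, 25.0)
    for R in glrlm_matrices(disc):
        lengths = np.arange(1, R.shape[1] + 1)
        assert (R * lengths).sum() == disc.mask.sum()


@pytest.mark.parametrize("seed", [0, 4])
def test_glszm_matrix_matches_flood_fill(seed):
    vm = _random_volume(np.random.default_rng(seed))
    disc = discretize(vm, 25.0)
    P = glszm_matrix(disc)
    expected = _brute_zones(disc.levels, disc.mask, disc.n_levels)
    w = max(P.shape[1], expected.shape[1])
    assert np.array_equal(
        np.pad(P, ((0, 0), (0, w - P.shape[1]))),
        np.pad(expected, ((0, 0), (0, w - expected.shape[1]))),
    )


@pytest.mark.parametrize("seed", [0, 6])
def test_gldm_matrix_matches_brute_force(seed):
    vm = _random_volume(np.random.default_rng(seed))
    disc = discretize(vm, 25.0)
    P = gldm_matrix(disc)
    expected = _brute_gldm(disc.levels, disc.mask, disc.n_levels)
    w = max(P.shape[1], expected.shape[1])
    assert np.array_equal(
        np.pad(P, ((0, 0), (0, w - P.shape[1]))),
        np.pad(expected, ((0, 0), (0, w - expected.shape[1]))),
    )
    assert P.sum() == disc.mask.sum()


@pytest.mark.parametrize("seed", [0, 8])
def test_ngtdm_table_matches_brute_force(seed):
    vm = _random_volume(np.random.default_rng(seed))
    disc = discretize(vm, 25.0)
    _, n_i, s_i = ngtdm_table(disc)
    en, es = _brute_ngtdm(disc.levels, disc.mask, disc.n_levels)
    assert np.array_equal(n_i, en)
    assert np.allclose(s_i, es, atol=1e-10)


# ------------------------------------------------------- hand-worked cases


def test_two_voxel_glcm_contrast_is_one():
    """Two adjacent voxels with levels {1,2}: the joining offset sees exactly
    two symmetric co-occurrences and Contrast = (1-2)^2 = 1."""
    image = np.zeros((2, 1, 1))
    image[1, 0, 0] = 25.0
    mask = np.ones((2, 1, 1), dtype=bool)
    disc = discretize(VolumeWithMask(image, mask, (1, 1, 1)), 25.0)
    mats = dict(zip(OFFSETS_13, glcm_matrices(disc)))
    joining = mats[(1, 0, 0)]
    assert joining.sum() == 2
    assert joining[0, 1] == 1 and joining[1, 0] == 1
    feats = extract_glcm(disc)
    assert feats["Contrast"] == pytest.approx(1.0)


def test_constant_roi_degenerate_texture_values():
    image = np.full((5, 5, 5), 60.0)
    mask = np.ones((5, 5, 5), dtype=bool)
    vm = VolumeWithMask(image, mask, (1, 1, 1))
    disc = discretize(vm, 25.0)
    fo = extract_firstorder(vm, disc)
    assert fo["Variance"] == 0.0
    assert fo["Entropy"] == 0.0
    glcm = extract_glcm(disc)
    assert glcm["Contrast"] == 0.0
    assert glcm["MaximumProbability"] == 1.0


def test_single_line_constant_roi_has_one_run_in_line_direction():
    """A 1xn constant line is a single run of length n along its axis; the
    run-length non-uniformity closed form for one run is 1."""
    n = 6
    image = np.full((n, 1, 1), 10.0)
    mask = np.ones((n, 1, 1), dtype=bool)
    disc = discretize(VolumeWithMask(image, mask, (1, 1, 1)), 25.0)
    mats = dict(zip(OFFSETS_13, glrlm_matrices(disc)))
    along = mats[(1, 0, 0)]
    assert along.shape == (1, n)
    assert along[0, -1] == 1 and along.sum() == 1
    # single run: RLN = (1^2)/1 = 1
    nr = along.sum()
    rln = (along.sum(axis=0) ** 2).sum() / nr
    assert rln == 1.0


# -------------------------------------------------- shape and first order


def test_sphere_sphericity_near_one(sphere_phantom):
    feats = extract_shape(sphere_phantom)
    assert abs(feats["Sphericity"] - 1.0) < 0.02


def test_sphere_diameters_near_analytic(sphere_phantom):
    feats = extract_shape(sphere_phantom)
    for name in ("Maximum3DDiameter", "Maximum2DDiameterSlice",
                 "Maximum2DDiameterColumn", "Maximum2DDiameterRow"):
        assert feats[name] == pytest.approx(20.0, rel=0.05)
    assert feats["Elongation"] == pytest.approx(1.0, abs=0.02)
    assert feats["Flatness"] == pytest.approx(1.0, abs=0.02)


def test_shape_invariant_to_intensity_rescale(textured_phantom):
    vm = textured_phantom
    scaled = VolumeWithMask(vm.image * 3.7 + 120.0, vm.mask, vm.spacing)
    assert extract_shape(vm) == extract_shape(scaled)


def test_firstorder_location_stats_shift_with_intensity():
    rng = np.random.default_rng(2)
    image = rng.uniform(0, 150, size=(6, 6, 6))
    mask = np.ones((6, 6, 6), dtype=bool)
    vm = VolumeWithMask(image, mask, (1, 1, 1))
    shifted = VolumeWithMask(image + 50.0, mask, (1, 1, 1))
    a = extract_firstorder(vm, discretize(vm, 25.0))
    b = extract_firstorder(shifted, discretize(shifted, 25.0))
    for name in ("Mean", "Median", "Minimum", "Maximum", "10Percentile", "90Percentile"):
        assert b[name] == pytest.approx(a[name] + 50.0, abs=1e-9)
    for name in ("Variance", "Entropy", "Skewness", "MeanAbsoluteDeviation", "Range"):
        assert b[name] == pytest.approx(a[name], abs=1e-9)


def test_firstorder_closed_forms_on_tiny_roi():
    image = np.zeros((4, 1, 1))
    image[:, 0, 0] = [2.0, 4.0, 4.0, 10.0]
    mask = np.ones((4, 1, 1), dtype=bool)
    vm = VolumeWithMask(image, mask, (1, 1, 2))
    fo = extract_firstorder(vm, discretize(vm, 25.0))
    assert fo["Mean"] == 5.0
    assert fo["Energy"] == 4 + 16 + 16 + 100
    assert fo["TotalEnergy"] == fo["Energy"] * 2.0
    assert fo["RootMeanSquared"] == pytest.approx(np.sqrt(136 / 4))
    assert fo["Variance"] == pytest.approx(np.mean(([2, 4, 4, 10] - np.float64(5)) ** 2))
    assert fo["Range"] == 8.0
    assert fo["Uniformity"] == 1.0  # all in one 25-HU bin


# ------------------------------------------------------------ full vector


def test_full_vector_contract(textured_phantom):
    fv = extract_all(textured_phantom)
    assert len(fv) == 107
    assert list(fv.index) == FEATURE_NAMES
    assert np.isfinite(fv.to_numpy()).all()
    counts = {fam: len(names) for fam, names in FAMILY_FEATURES.items()}
    assert counts == {"shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
                      "glszm": 16, "gldm": 14, "ngtdm": 5}


def test_extraction_is_deterministic(textured_phantom):
    a = extract_all(textured_phantom)
    b = extract_all(textured_phantom)
    assert np.array_equal(a.to_numpy(), b.to_numpy())


def test_texture_invariant_to_intensity_shift(textured_phantom):
    """Min-referenced discretization makes every texture family shift-invariant."""
    vm = textured_phantom
    shifted = VolumeWithMask(vm.image + 77.0, vm.mask, vm.spacing)
    cfg = ExtractionConfig(do_resample=False)
    a = extract_all(vm, cfg)
    b = extract_all(shifted, cfg)
    texture = [n for n in FEATURE_NAMES
               if n.split("/")[0] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")]
    assert np.allclose(a[texture], b[texture], rtol=1e-12)


def test_single_voxel_roi_warns_but_stays_finite():
    image = np.full((5, 5, 5), 30.0)
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    vm = VolumeWithMask(image, mask, (1, 1, 1))
    with pytest.warns(UserWarning, match="degenerate"):
        fv = extract_all(vm, ExtractionConfig(do_resample=False))
    assert np.isfinite(fv.to_numpy()).all()
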