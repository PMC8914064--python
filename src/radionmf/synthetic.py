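"""Synthetic phantoms and cohorts with the statistical structure the analysis assumes.

Two generators:

* ``make_phantom`` — lesion phantoms on a voxel grid with physical spacing:
  an analytic sphere/ellipsoid (mask = voxels whose centre lies inside the
  surface) or a "textured blob" whose surface is perturbed by a smooth random
  field and whose interior carries a correlated HU texture.  These stand in
  for contrast-enhanced CT acquisitions with a delineated lesion.

* ``make_cohort`` — nonnegative feature-by-sample matrices V = W H + noise
  with a planted low-rank structure in which one component's per-sample
  score drives an exponential proportional-hazards failure process.  The
  default settings emulate a training-like cohort: N = 104 samples with an
  ~11% failure fraction by 12 months (the validation-like preset uses
  N = 24 with ~46% failure).

All randomness flows from the spec's single ``seed`` through one named
``numpy.random.Generator``; no global random state is touched.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .volume import VolumeWithMask, save_nifti_pair

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_phantom",
    "make_cohort",
    "baseline_hazard_for_target",
    "write_cohort_csv",
    "write_phantom_nifti",
]


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of a lesion phantom on a voxel grid.

    lesion_params holds ``radii`` (mm, one value for a sphere, three for an
    ellipsoid/blob) and optionally ``center`` (mm; defaults to the grid
    centre).  HU values: urine-like background and soft-tissue-like lesion.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    lesion_kind: str = "sphere"  # sphere | ellipsoid | textured_blob
    lesion_params: dict = dataclasses.field(default_factory=lambda: {"radii": 10.0})
    background_hu: float = 5.0
    lesion_hu: float = 45.0
    noise_sd: float = 0.0
    seed: int = 0

    # surface perturbation amplitude for textured_blob, fraction of radius
    blob_amplitude: float = 0.15
    # peak amplitude (HU) of the correlated intra-lesion texture field for
    # textured_blob; None defaults to the lesion-background contrast, giving
    # a grey-level spread comparable to heterogeneous contrast enhancement
    texture_amplitude_hu: float | None = None

    def radii_mm(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.lesion_params["radii"], dtype=float))
        if r.size == 1:
            r = np.repeat(r, 3)
        if r.size != 3 or (r <= 0).any():
            raise ValueError(f"radii must be 1 or 3 positive values, got {r}")
        return r

    def center_mm(self) -> np.ndarray:
        if "center" in self.lesion_params:
            return np.asarray(self.lesion_params["center"], dtype=float)
        extent = (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)
        return extent / 2.0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 2 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 axes of >=2 voxels, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.lesion_kind not in ("sphere", "ellipsoid", "textured_blob"):
            raise ValueError(f"unknown lesion_kind {self.lesion_kind!r}")
        radii = self.radii_mm()
        margin = 1.0 + (self.blob_amplitude if self.lesion_kind == "textured_blob" else 0.0)
        center = self.center_mm()
        extent = (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing)
        lo = center - radii * margin
        hi = center + radii * margin
        if (lo < 0).any() or (hi > extent).any():
            raise ValueError(
                f"lesion (radii {radii} mm, centre {center} mm) does not fit "
                f"inside the grid extent {extent} mm"
            )


def _smooth_field(rng: np.random.Generator, shape, sigma_voxels: float) -> np.ndarray:
    """White noise smoothed to a correlated field, rescaled to unit max-abs."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_voxels)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def make_phantom(spec: PhantomSpec) -> VolumeWithMask:
    """Build a lesion phantom; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing)
    radii = spec.radii_mm()
    center = spec.center_mm()

    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(spec.grid_shape, spacing)], indexing="ij"
    )
    # normalized ellipsoid distance of each voxel centre
    d = np.sqrt(sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii)))

    if spec.lesion_kind in ("sphere", "ellipsoid"):
        mask = d <= 1.0
    else:  # textured_blob: surface radius modulated by a smooth random field
        bump = _smooth_field(rng, spec.grid_shape, sigma_voxels=3.0)
        mask = d <= 1.0 + spec.blob_amplitude * bump

    image = np.full(spec.grid_shape, float(spec.background_hu))
    image[mask] = spec.lesion_hu
    if spec.lesion_kind == "textured_blob":
        amp = (
            spec.texture_amplitude_hu
            if spec.texture_amplitude_hu is not None
            else abs(spec.lesion_hu - spec.background_hu)
        )
        texture = _smooth_field(rng, spec.grid_shape, sigma_voxels=1.5)
        image[mask] += texture[mask] * amp
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    return VolumeWithMask(image, mask, tuple(spacing))


@dataclasses.dataclass
class CohortSpec:
    """Parameters of a planted-low-rank radiomics cohort.

    One row of the planted H (``hazard_component_index``) drives an
    exponential proportional-hazards failure process: subject hazard is
    ``baseline_hazard * exp(log_hazard_ratio * z)`` with z the z-scored
    component score.  If ``baseline_hazard`` is None it is calibrated so the
    expected failure fraction by ``failure_horizon`` equals
    ``target_failure_rate``.  Censoring is administrative at
    ``censoring_time`` months.
    """

    n_samples: int = 104
    n_features: int = 54
    true_rank: int = 5
    component_sparsity: float = 0.6
    noise_sd: float = 0.05
    hazard_component_index: int = 2
    log_hazard_ratio: float = 0.8
    baseline_hazard: float | None = None
    target_failure_rate: float = 0.11
    censoring_time: float = 24.0
    failure_horizon: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if not (1 <= self.true_rank < min(self.n_features, self.n_samples)):
            raise ValueError(
                f"true_rank {self.true_rank} must be in [1, min(M, N)) = "
                f"[1, {min(self.n_features, self.n_samples)})"
            )
        if not (0 <= self.hazard_component_index < self.true_rank):
            raise ValueError("hazard_component_index out of range")
        if not (0.0 <= self.component_sparsity < 1.0):
            raise ValueError("component_sparsity must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.censoring_time <= 0 or self.failure_horizon <= 0:
            raise ValueError("times must be positive")


def baseline_hazard_for_target(
    target: float,
    log_hazard_ratio: float,
    horizon: float,
    z: np.ndarray | None = None,
) -> float:
    """Baseline hazard (events/month) giving an expected failure fraction.

    Solves E_z[1 - exp(-horizon * lam * exp(beta * z))] = target by
    bisection.  The expectation is taken over the supplied covariate values
    ``z`` when given (exact for a realized cohort), otherwise over
    z ~ N(0, 1) by Gauss-Hermite quadrature.
    """
    if not (0 < target < 1):
        raise ValueError("target failure fraction must be in (0, 1)")
    if z is None:
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        weights = weights / weights.sum()
    else:
        nodes = np.asarray(z, dtype=np.float64)
        weights = np.full(nodes.size, 1.0 / nodes.size)

    def expected(lam: float) -> float:
        return float(
            (weights * (1.0 - np.exp(-horizon * lam * np.exp(log_hazard_ratio * nodes)))).sum()
        )

    return float(optimize.brentq(lambda lam: expected(lam) - target, 1e-10, 10.0))


def make_cohort(spec: CohortSpec, planted_W: np.ndarray | None = None):
    """Generate (FeatureMatrix-ready frame, survival frame, W_true, H_true).

    Pass ``planted_W`` (the W_true of a previous call) to draw an
    independent validation-like cohort from the same feature-generating
    process: new samples, same planted metafeature dictionary.

    Returns
    -------
    features : pandas.DataFrame, shape (n_features, n_samples), all >= 0
    clinical : pandas.DataFrame with columns sample_id, time_months, event,
        failure_12mo (the horizon label), plus a ``warning`` attr flag when
        the configuration yields zero events or zero censored subjects
    W_true, H_true : the planted factors
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    M, N, k = spec.n_features, spec.n_samples, spec.true_rank

    if planted_W is not None:
        W = np.asarray(planted_W, dtype=np.float64)
        if W.shape != (M, k):
            raise ValueError(f"planted_W must have shape {(M, k)}, got {W.shape}")
    else:
        W = rng.uniform(0.2, 1.0, size=(M, k))
        # sparsify: most features load on few components
        zero = rng.random(size=(M, k)) < spec.component_sparsity
        W[zero] *= 0.01
        # equalize planted component strength so no component degenerates
        W /= np.linalg.norm(W, axis=0, keepdims=True)
        W *= np.sqrt(M) * 0.5
    # archetypal sample structure: each sample is dominated by one component
    # (radiomics subtypes), with balanced subtype sizes and low background
    # levels on the other components
    dominant = rng.permutation(np.resize(np.arange(k), N))
    H = rng.uniform(0.0, 0.25, size=(k, N))
    H[dominant, np.arange(N)] = rng.uniform(0.7, 1.0, size=N)

    V = W @ H
    if spec.noise_sd > 0:
        V = V + rng.normal(0.0, spec.noise_sd, size=V.shape)
    V = np.clip(V, 0.0, None)

    h = H[spec.hazard_component_index]
    z = (h - h.mean()) / h.std()
    lam0 = (
        spec.baseline_hazard
        if spec.baseline_hazard is not None
        else baseline_hazard_for_target(
            spec.target_failure_rate, spec.log_hazard_ratio, spec.failure_horizon, z=z
        )
    )
    rate = lam0 * np.exp(spec.log_hazard_ratio * z)
    t_fail = rng.exponential(1.0 / rate)
    event = (t_fail <= spec.censoring_time).astype(int)
    time = np.minimum(t_fail, spec.censoring_time)
    failure = ((event == 1) & (time <= spec.failure_horizon)).astype(int)

    sample_ids = [f"S{j:03d}" for j in range(N)]
    feature_names = [f"F{i:03d}" for i in range(M)]
    features = pd.DataFrame(V, index=feature_names, columns=sample_ids)
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time_months": time,
            "event": event,
            "failure_12mo": failure,
        }
    )
    if event.sum() == 0 or event.sum() == N:
        warnings.warn(
            "degenerate cohort: zero events or zero censored subjects",
            stacklevel=2,
        )
        clinical.attrs["warning"] = "degenerate_events"
    return features, clinical, W, H


def write_phantom_nifti(vm: VolumeWithMask, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a phantom as a paired NIfTI image + mask."""
    save_nifti_pair(vm, image_path, mask_path)


def write_cohort_csv(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    features_path: str | Path,
    clinical_path: str | Path,
) -> None:
    """Write a cohort: features (rows = features, cols = samples) and clinical table."""
    features.to_csv(features_path)
    clinical.to_csv(clinical_path, index=False)
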