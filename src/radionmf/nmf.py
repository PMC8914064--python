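"""Nonnegative matrix factorization with multiplicative updates.

Factorizes a nonnegative feature-by-sample matrix V (M x N) as V ~ W H with
W (M x k) holding the metafeature loadings and H (k x N) the per-sample
component levels.  The Frobenius objective ||V - WH||^2 is minimized by the
classic multiplicative update rules, which keep both factors nonnegative and
never increase the objective:

    H <- H * (W^T V) / (W^T W H + eps)
    W <- W * (V H^T) / (W H H^T + eps)

Rank selection scans a grid of k with many random restarts per k, keeps the
best residual sum of squares (RSS) at each k, and picks the rank where the
RSS curve bends: the interior point maximizing the discrete second
difference.  After fitting, W columns are normalized to unit Euclidean norm
(scale absorbed into H) so the per-sample component scores, and the z-score
cutoff applied to them, are well defined.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy import optimize

__all__ = [
    "NMFDecomposition",
    "RssCurve",
    "ComponentScores",
    "factorize",
    "rss_curve",
    "select_rank",
    "standardize_scores",
    "apply_standardization",
    "project_cohort",
]

_EPS = 1e-10


@dataclasses.dataclass
class NMFDecomposition:
    """One fitted factorization V ~ W H.

    W columns are unit-Euclidean-norm; rss is the Frobenius residual
    ||V - WH||^2 at the final iterate; rss_history records the objective at
    every iteration (non-increasing by the multiplicative-update theorem).
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    rss: float
    n_iter: int
    seed: int | tuple
    converged: bool
    rss_history: np.ndarray

    def save(self, prefix: str | Path) -> None:
        """Serialize as <prefix>_W.csv, <prefix>_H.csv, <prefix>_meta.json."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_name(prefix.name + "_W.csv"), self.W, delimiter=",")
        np.savetxt(prefix.with_name(prefix.name + "_H.csv"), self.H, delimiter=",")
        meta = {
            "k": self.k,
            "rss": self.rss,
            "n_iter": self.n_iter,
            "seed": list(self.seed) if isinstance(self.seed, tuple) else self.seed,
            "converged": self.converged,
        }
        prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps(meta, indent=1))


@dataclasses.dataclass
class RssCurve:
    """Best-of-restarts RSS per candidate rank."""

    ks: np.ndarray
    rss: np.ndarray
    n_restarts: int


@dataclasses.dataclass
class ComponentScores:
    """Rows of H standardized to mean 0, sd 1 (population sd) across training
    samples; the stored per-row mean/sd are frozen for new cohorts."""

    z: np.ndarray
    mean: np.ndarray
    sd: np.ndarray


def _init_factors(V: np.ndarray, k: int, rng: np.random.Generator):
    # entries uniform on (0, 1] scaled by mean(V)
    scale = V.mean()
    W = (1.0 - rng.random((V.shape[0], k))) * scale
    H = (1.0 - rng.random((k, V.shape[1]))) * scale
    return W, H


def factorize(
    V: np.ndarray,
    k: int,
    seed: int | tuple = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFDecomposition:
    """Multiplicative-update NMF of V at rank k from one random start.

    Stops when the relative RSS change per iteration falls below ``tol`` or
    after ``max_iter`` iterations.  ``seed`` may be an int or a tuple (fed
    to numpy's SeedSequence), letting restart seeds derive deterministically
    from a master seed.
    """
    V = np.asarray(V, dtype=np.float64)
    if V.ndim != 2:
        raise ValueError("V must be 2D")
    if (V < 0).any():
        raise ValueError("V has negative entries; NMF requires V >= 0")
    if not (1 <= k < min(V.shape)):
        raise ValueError(f"rank k={k} out of range [1, {min(V.shape)})")

    rng = np.random.default_rng(seed)
    W, H = _init_factors(V, k, rng)

    history = []
    rss = float(((V - W @ H) ** 2).sum())
    history.append(rss)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        new_rss = float(((V - W @ H) ** 2).sum())
        history.append(new_rss)
        if rss > 0 and abs(rss - new_rss) / rss < tol:
            rss = new_rss
            converged = True
            break
        rss = new_rss

    # normalize W columns to unit Euclidean norm, absorb scale into H
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms
    H = H * norms[:, None]

    return NMFDecomposition(
        W=W,
        H=H,
        k=k,
        rss=rss,
        n_iter=it,
        seed=seed,
        converged=converged,
        rss_history=np.asarray(history),
    )


def rss_curve(
    V: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    n_restarts: int = 100,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> RssCurve:
    """Best RSS over ``n_restarts`` random restarts for each k in the grid.

    Restart seeds derive deterministically from ``(seed, k, restart)``, so
    the curve is bit-reproducible for a fixed master seed.
    """
    V = np.asarray(V, dtype=np.float64)
    if k_max >= min(V.shape):
        raise ValueError(f"k_max={k_max} must be < min(M, N)={min(V.shape)}")
    ks = np.arange(k_min, k_max + 1)
    best = np.empty(len(ks))
    for i, k in enumerate(ks):
        best[i] = min(
            factorize(V, int(k), seed=(seed, int(k), r), max_iter=max_iter, tol=tol).rss
            for r in range(n_restarts)
        )
    return RssCurve(ks=ks, rss=best, n_restarts=n_restarts)


def select_rank(curve: RssCurve) -> int:
    """Rank at the bend of the RSS curve.

    Returns the interior grid value maximizing the discrete second
    difference rss(k-1) - 2 rss(k) + rss(k+1); ties break toward smaller k.
    A flat curve returns the smallest k with a warning.
    """
    if len(curve.ks) < 3:
        raise ValueError("need at least 3 points on the RSS curve")
    r = curve.rss
    if np.allclose(r, r[0]):
        warnings.warn("flat RSS curve; returning k_min", stacklevel=2)
        return int(curve.ks[0])
    second = r[:-2] - 2.0 * r[1:-1] + r[2:]
    best = int(np.argmax(second))  # argmax takes the first (smallest k) on ties
    return int(curve.ks[1 + best])


def standardize_scores(H: np.ndarray) -> ComponentScores:
    """Standardize each row of H to mean 0, sd 1 (population sd)."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    mean = H.mean(axis=1)
    sd = H.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance component row cannot be standardized")
    z = (H - mean[:, None]) / sd[:, None]
    return ComponentScores(z=z, mean=mean, sd=sd)


def apply_standardization(H_new: np.ndarray, scores: ComponentScores) -> np.ndarray:
    """Apply frozen training means/sds to a new cohort's H."""
    H_new = np.asarray(H_new, dtype=np.float64)
    if H_new.shape[0] != scores.mean.shape[0]:
        raise ValueError("component count mismatch with stored parameters")
    return (H_new - scores.mean[:, None]) / scores.sd[:, None]


def project_cohort(W: np.ndarray, V_new: np.ndarray) -> np.ndarray:
    """Component levels of new samples under a trained W.

    Solves, per sample column, the nonnegative least squares problem
    H[:, j] = argmin_{h >= 0} ||V_new[:, j] - W h||^2.
    """
    W = np.asarray(W, dtype=np.float64)
    V_new = np.asarray(V_new, dtype=np.float64)
    if V_new.shape[0] != W.shape[0]:
        raise ValueError(
            f"feature mismatch: W has {W.shape[0]} rows, V_new has {V_new.shape[0]}"
        )
    if (V_new < 0).any():
        raise ValueError("V_new has negative entries")
    H = np.empty((W.shape[1], V_new.shape[1]))
    for j in range(V_new.shape[1]):
        H[:, j], _ = optimize.nnls(W, V_new[:, j])
    return H
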