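"""End-to-end orchestration: preprocess -> factorize -> select -> evaluate.

``run_training`` takes a raw nonnegative feature-by-sample matrix and a
clinical table, fits the whole analysis, and returns a ``TrainedModel``
whose frozen parameters (retained feature list, min-max scaling, W, z-score
means/sds, selected component, cutoff) let ``run_validation`` evaluate an
independent cohort with no refitting: new samples are projected onto the
trained components by nonnegative least squares and thresholded at the
training cutoff.

A single master seed drives every stochastic stage; per-stage seeds are
derived deterministically, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import nmf
from .evaluate import EvaluationReport, evaluate_predictions, youden_cutoff
from .preprocess import (
    FeatureMatrix,
    apply_scaling,
    collinearity_filter,
    nonnegative_scale,
)
from .survival import (
    ComponentSelection,
    SurvivalCohort,
    predicted_failure_risk,
    select_component,
)

__all__ = ["RunConfig", "TrainedModel", "run_training", "run_validation"]


def _stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Settings of one reproducible training run."""

    r_threshold: float = 0.90
    k_min: int = 2
    k_max: int = 10
    n_restarts: int = 100
    seed: int = 0
    cutoff_policy: str = "youden"  # "youden" | "fixed"
    fixed_cutoff: float = 0.2
    horizon_months: float = 12.0
    max_iter: int = 2000
    tol: float = 1e-6

    def validate(self) -> None:
        if self.cutoff_policy not in ("youden", "fixed"):
            raise ValueError(f"unknown cutoff policy {self.cutoff_policy!r}")
        if not (2 <= self.k_min < self.k_max):
            raise ValueError("need 2 <= k_min < k_max")


@dataclasses.dataclass
class TrainedModel:
    """Everything frozen at training time, sufficient to score new cohorts."""

    config: RunConfig
    scaled: FeatureMatrix  # carries retained feature names + min/max params
    dropped_features: list[str]
    decomposition: nmf.NMFDecomposition
    rss_curve: nmf.RssCurve
    scores: nmf.ComponentScores
    selection: ComponentSelection
    cutoff: float
    report: EvaluationReport
    cohort: SurvivalCohort

    @property
    def selected_component(self) -> int:
        return self.selection.selected

    def frozen_checksum(self) -> str:
        """Checksum over every frozen training-time parameter.

        Validation must leave this unchanged; the pipeline asserts it.
        """
        h = hashlib.sha256()
        for arr in (
            self.scaled.scale_min,
            self.scaled.scale_max,
            self.decomposition.W,
            self.scores.mean,
            self.scores.sd,
            np.array([self.cutoff, self.selection.selected, self.selection.sign]),
        ):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(self.scaled.feature_names).encode())
        return h.hexdigest()

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scaled.save_params(out / "preprocess.json", self.dropped_features)
        self.decomposition.save(out / "decomposition")
        (out / "selection.json").write_text(
            json.dumps(
                {
                    "selected_component": self.selection.selected,
                    "sign": self.selection.sign,
                    "cutoff": self.cutoff,
                    "per_component": self.selection.table().to_dict("records"),
                    "score_mean": self.scores.mean.tolist(),
                    "score_sd": self.scores.sd.tolist(),
                    "seed": self.config.seed,
                    "frozen_checksum": self.frozen_checksum(),
                },
                indent=1,
            )
        )
        (out / "training_report.json").write_text(self.report.to_json())


def _align_cohort(fm: FeatureMatrix, cohort: SurvivalCohort) -> SurvivalCohort:
    if list(cohort.sample_ids) == list(fm.sample_ids):
        return cohort
    pos = {s: i for i, s in enumerate(cohort.sample_ids)}
    missing = [s for s in fm.sample_ids if s not in pos]
    if missing:
        raise ValueError(f"clinical table is missing samples: {missing[:5]}")
    idx = np.array([pos[s] for s in fm.sample_ids])
    return cohort.subset(idx)


def run_training(
    features: FeatureMatrix, cohort: SurvivalCohort, config: RunConfig | None = None
) -> TrainedModel:
    """Fit the full analysis on a training cohort.

    ``features`` is the raw (unscaled) feature-by-sample matrix; the clinical
    ``cohort`` is aligned to its sample columns by id.
    """
    config = config or RunConfig()
    config.validate()
    if len(features.sample_ids) == 0:
        raise ValueError("empty cohort")
    cohort = _align_cohort(features, cohort)

    filtered, dropped = collinearity_filter(features, config.r_threshold)
    scaled = nonnegative_scale(filtered)

    curve = nmf.rss_curve(
        scaled.values,
        k_min=config.k_min,
        k_max=config.k_max,
        n_restarts=config.n_restarts,
        seed=_stage_seed(config.seed, "nmf"),
        max_iter=config.max_iter,
        tol=config.tol,
    )
    k = nmf.select_rank(curve)
    # refit at the chosen rank: keep the best-rss restart
    nmf_seed = _stage_seed(config.seed, "nmf")
    decomp = min(
        (
            nmf.factorize(
                scaled.values, k, seed=(nmf_seed, k, r),
                max_iter=config.max_iter, tol=config.tol,
            )
            for r in range(config.n_restarts)
        ),
        key=lambda d: d.rss,
    )

    # Score samples by NNLS projection onto the trained dictionary W rather
    # than by the factorization's own H: validation cohorts can only be
    # scored by projection, and using the identical scoring path for the
    # training cohort makes training and validation exactly consistent.
    H_scores = nmf.project_cohort(decomp.W, scaled.values)
    scores = nmf.standardize_scores(H_scores)
    selection = select_component(scores, cohort)
    risk = selection.risk_scores(scores.z)

    if config.cutoff_policy == "fixed":
        cutoff = config.fixed_cutoff
    else:
        cutoff, _ = youden_cutoff(risk, cohort.failure_12mo)

    fit = selection.fits[selection.selected]
    predicted = predicted_failure_risk(
        fit.beta, selection.sign * scores.z[selection.selected], cohort,
        config.horizon_months,
    )
    report = evaluate_predictions(
        risk, cohort, cutoff, predicted_risk=predicted,
        horizon_months=config.horizon_months,
    )
    return TrainedModel(
        config=config,
        scaled=scaled,
        dropped_features=dropped,
        decomposition=decomp,
        rss_curve=curve,
        scores=scores,
        selection=selection,
        cutoff=cutoff,
        report=report,
        cohort=cohort,
    )


def run_validation(
    model: TrainedModel, features: FeatureMatrix, cohort: SurvivalCohort
) -> EvaluationReport:
    """Evaluate an independent cohort under the frozen trained model.

    Applies the training-frozen feature list and min-max parameters,
    projects samples onto the trained W by nonnegative least squares,
    standardizes with the frozen means/sds, and thresholds at the frozen
    cutoff.  No training-time quantity is recomputed (checksum-asserted).
    """
    if len(features.sample_ids) == 0:
        raise ValueError("empty validation cohort")
    before = model.frozen_checksum()
    cohort = _align_cohort(features, cohort)

    scaled = apply_scaling(model.scaled, features)
    H_new = nmf.project_cohort(model.decomposition.W, scaled.values)
    z_new = nmf.apply_standardization(H_new, model.scores)
    risk = model.selection.risk_scores(z_new)

    # absolute risks for the new cohort under the frozen training baseline
    fit = model.selection.fits[model.selection.selected]
    from .survival import breslow_cumulative_hazard

    times, h0 = breslow_cumulative_hazard(
        fit.beta,
        model.selection.sign * model.scores.z[model.selection.selected],
        model.cohort,
    )
    mask = times <= model.config.horizon_months
    h0_at = float(h0[mask][-1]) if mask.any() else 0.0
    predicted_new = 1.0 - np.exp(-h0_at * np.exp(fit.beta * risk))

    report = evaluate_predictions(
        risk,
        cohort,
        model.cutoff,
        predicted_risk=predicted_new,
        horizon_months=model.config.horizon_months,
    )
    if model.frozen_checksum() != before:
        raise RuntimeError("frozen training parameters changed during validation")
    return report
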