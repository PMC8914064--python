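"""Predictive and prognostic performance measures.

Predictive: ROC/AUC (Mann-Whitney formulation), Youden-index cutoff,
confusion metrics at a cutoff.  Prognostic: Kaplan-Meier product-limit
curves with the two-group log-rank test, Harrell's C-index (in
:mod:`radionmf.survival`), model calibration at a horizon, and decision-curve
net benefit.  ICC (two-way, absolute agreement, single measurement)
quantifies segmentation reproducibility.

A positive classification call is ``score >= cutoff`` (inclusive boundary).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
from scipy import stats

from .survival import SurvivalCohort

__all__ = [
    "ConfusionResult",
    "KMCurve",
    "EvaluationReport",
    "roc_auc",
    "youden_cutoff",
    "confusion_at",
    "km_estimate",
    "logrank",
    "calibration_curve",
    "decision_curve",
    "icc",
    "evaluate_predictions",
]


def _check_two_classes(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not np.isin(u, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if len(u) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the probability that a random positive scores above a random
    negative; tied scores contribute 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Every observed score is evaluated as the cutoff of the rule
    "positive iff score >= cutoff"; ties in J break toward the smallest
    cutoff.  Returns (cutoff, J).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    best_cut, best_j = np.inf, -np.inf
    for cut in np.sort(np.unique(scores)):
        called = scores >= cut
        sens = (called & (labels == 1)).sum() / n_pos
        spec = (~called & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and cut < best_cut):
            best_cut, best_j = float(cut), float(j)
    return best_cut, best_j


@dataclasses.dataclass
class ConfusionResult:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def confusion_at(scores: np.ndarray, labels: np.ndarray, cutoff: float) -> ConfusionResult:
    """Confusion counts calling positive iff score >= cutoff."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    called = scores >= cutoff
    return ConfusionResult(
        tp=int((called & (labels == 1)).sum()),
        fp=int((called & (labels == 0)).sum()),
        tn=int((~called & (labels == 0)).sum()),
        fn=int((~called & (labels == 1)).sum()),
    )


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival estimate of one group."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each time
    median: float | None  # earliest time with S <= 0.5, None if never reached

    def at(self, t: float) -> float:
        """S(t); 1.0 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(cohort: SurvivalCohort, groups: np.ndarray | None = None) -> dict:
    """Kaplan-Meier curves per group label (single group when ``groups`` is None)."""
    if groups is None:
        groups = np.zeros(len(cohort), dtype=int)
    groups = np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size == 0:
            raise ValueError(f"group {g} is empty")
        t = cohort.time_months[idx]
        e = cohort.event[idx]
        times = np.unique(t[e == 1])
        s = 1.0
        surv = []
        for tt in times:
            d = int(((t == tt) & (e == 1)).sum())
            n = int((t >= tt).sum())
            s *= 1.0 - d / n
            surv.append(s)
        surv = np.asarray(surv)
        below = np.flatnonzero(surv <= 0.5)
        median = float(times[below[0]]) if below.size else None
        out[g] = KMCurve(times=times, survival=surv, median=median)
    return out


def logrank(cohort: SurvivalCohort, groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if cohort.event.sum() == 0:
        raise ValueError("no events")
    t = cohort.time_months
    e = cohort.event
    g1 = groups == labels[1]
    obs1 = 0.0
    exp1 = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((t == tt) & (e == 1)).sum())
        d1 = int(((t == tt) & (e == 1) & g1).sum())
        obs1 += d1
        exp1 += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = (obs1 - exp1) ** 2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def calibration_curve(
    predicted_risk: np.ndarray,
    cohort: SurvivalCohort,
    horizon_months: float = 12.0,
    n_bins: int = 3,
) -> list[tuple[float, float]]:
    """Observed vs predicted failure-by-horizon probability in quantile bins.

    Per bin: (mean predicted risk, 1 - KM survival at the horizon within the
    bin).  Bins follow the quantiles of the predicted risk; when predictions
    tie heavily fewer (possibly one) bins are produced.
    """
    r = np.asarray(predicted_risk, dtype=np.float64)
    if ((r < 0) | (r > 1)).any():
        raise ValueError("predicted risks must lie in [0, 1]")
    if horizon_months > cohort.time_months.max():
        warnings.warn(
            "horizon is beyond the last observed time; observed fractions are "
            "extrapolated from the final KM value",
            stacklevel=2,
        )
    edges = np.unique(np.quantile(r, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:  # constant predictions: a single bin
        bins = np.zeros(len(r), dtype=int)
    else:
        bins = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(edges) - 2)
    points = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        km = km_estimate(cohort.subset(idx))[0]
        observed = 1.0 - km.at(horizon_months)
        points.append((float(r[idx].mean()), float(observed)))
    return points


def decision_curve(
    predicted_risk: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray,
) -> dict[str, np.ndarray]:
    """Net benefit of the model, treat-all and treat-none across thresholds.

    net benefit at p_t = TP/n - (FP/n) * p_t / (1 - p_t), calling positive
    iff predicted risk >= p_t.  Thresholds outside (0, 1) are excluded.
    """
    r = np.asarray(predicted_risk, dtype=np.float64)
    labels = np.asarray(labels)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    thresholds = thresholds[(thresholds > 0) & (thresholds < 1)]
    n = len(r)
    prevalence = (labels == 1).mean()
    model = []
    for pt in thresholds:
        called = r >= pt
        tp = (called & (labels == 1)).sum()
        fp = (called & (labels == 0)).sum()
        model.append(tp / n - (fp / n) * pt / (1 - pt))
    odds = thresholds / (1 - thresholds)
    return {
        "thresholds": thresholds,
        "net_benefit": np.asarray(model),
        "treat_all": prevalence - (1 - prevalence) * odds,
        "treat_none": np.zeros_like(thresholds),
    }


def icc(ratings: np.ndarray) -> float:
    """Two-way, absolute-agreement, single-measurement intraclass correlation.

    ``ratings`` is subjects x repeated measurements.  Computed from the
    standard two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR/MSC/MSE the subject, rater and residual mean squares.
    """
    Y = np.asarray(ratings, dtype=np.float64)
    if Y.ndim != 2 or Y.shape[0] < 2 or Y.shape[1] < 2:
        raise ValueError("ratings must be (>=2 subjects) x (>=2 measurements)")
    n, k = Y.shape
    mean = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - mean) ** 2).sum()
    ss_cols = n * ((col_means - mean) ** 2).sum()
    ss_total = ((Y - mean) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        if ss_rows == 0:
            warnings.warn("zero between-subject variance; ICC set to 0", stacklevel=2)
            return 0.0
    return float((msr - mse) / denom)


@dataclasses.dataclass
class EvaluationReport:
    """Bundle of predictive + prognostic results for one cohort."""

    auc: float
    cutoff: float
    confusion: ConfusionResult
    c_index: float
    km_groups: np.ndarray
    logrank_statistic: float
    logrank_p: float
    calibration_points: list[tuple[float, float]] | None = None
    net_benefit: dict[str, np.ndarray] | None = None

    def to_json(self) -> str:
        payload = {
            "auc": self.auc,
            "cutoff": self.cutoff,
            "confusion": self.confusion.as_dict(),
            "c_index": self.c_index,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": round(self.logrank_p, 3),
        }
        if self.calibration_points is not None:
            payload["calibration_points"] = self.calibration_points
        if self.net_benefit is not None:
            payload["net_benefit"] = {
                k: np.asarray(v).tolist() for k, v in self.net_benefit.items()
            }
        return json.dumps(payload, indent=1)


def evaluate_predictions(
    risk_scores: np.ndarray,
    cohort: SurvivalCohort,
    cutoff: float,
    predicted_risk: np.ndarray | None = None,
    horizon_months: float = 12.0,
) -> EvaluationReport:
    """Full evaluation of an oriented risk score against a cohort.

    ``cutoff`` is applied as-is (it is frozen from training when evaluating
    a validation cohort).  ``predicted_risk`` (absolute failure
    probabilities) enables the calibration and decision curves.
    """
    from .survival import c_index as harrell_c

    labels = cohort.failure_12mo
    auc = roc_auc(risk_scores, labels)
    conf = confusion_at(risk_scores, labels, cutoff)
    groups = (np.asarray(risk_scores) >= cutoff).astype(int)
    if len(np.unique(groups)) == 2:
        lr_stat, lr_p = logrank(cohort, groups)
    else:
        lr_stat, lr_p = 0.0, 1.0
    report = EvaluationReport(
        auc=auc,
        cutoff=float(cutoff),
        confusion=conf,
        c_index=harrell_c(risk_scores, cohort),
        km_groups=groups,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
    )
    if predicted_risk is not None:
        report.calibration_points = calibration_curve(
            predicted_risk, cohort, horizon_months
        )
        report.net_benefit = decision_curve(
            predicted_risk, labels, np.linspace(0.05, 0.95, 19)
        )
    return report
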