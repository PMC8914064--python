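"""Single-covariate Cox proportional-hazards fitting and component selection.

Each metafeature's z-scored per-sample level is fit as the sole covariate of
a Cox model on recurrence-free survival; the component with the highest
Harrell's concordance index is selected as the risk score.  The partial
likelihood is maximized by Newton-Raphson with the Efron correction for
tied event times (months-granularity follow-up produces heavy ties).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .nmf import ComponentScores

__all__ = [
    "SurvivalCohort",
    "CoxFit",
    "ComponentSelection",
    "cox_fit",
    "c_index",
    "select_component",
    "breslow_cumulative_hazard",
    "predicted_failure_risk",
]

_BETA_CAP = 20.0


@dataclasses.dataclass
class SurvivalCohort:
    """Per-sample time-to-event data aligned with feature-matrix columns.

    time_months > 0; event is 1 for observed BCG failure (high-grade
    recurrence), 0 for censoring; failure_12mo is the binary
    failure-within-horizon label (event within 12 months by default).
    """

    sample_ids: list[str]
    time_months: np.ndarray
    event: np.ndarray
    failure_12mo: np.ndarray | None = None
    horizon_months: float = 12.0

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time_months = np.asarray(self.time_months, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        n = len(self.sample_ids)
        if self.time_months.shape != (n,) or self.event.shape != (n,):
            raise ValueError("sample_ids, time_months and event must align")
        if (self.time_months <= 0).any():
            raise ValueError("event/censoring times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        derived = ((self.event == 1) & (self.time_months <= self.horizon_months)).astype(int)
        if self.failure_12mo is None:
            self.failure_12mo = derived
        else:
            self.failure_12mo = np.asarray(self.failure_12mo, dtype=np.int64)
            if not np.array_equal(self.failure_12mo, derived):
                raise ValueError(
                    "failure_12mo inconsistent with event & time <= horizon"
                )

    def __len__(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_csv(cls, path: str | Path, horizon_months: float = 12.0) -> "SurvivalCohort":
        """Read a clinical table (sample_id, time_months, event[, failure_12mo])."""
        df = pd.read_csv(path)
        required = {"sample_id", "time_months", "event"}
        if not required.issubset(df.columns):
            raise ValueError(f"clinical CSV must have columns {sorted(required)}")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            time_months=df["time_months"].to_numpy(),
            event=df["event"].to_numpy(),
            failure_12mo=(
                df["failure_12mo"].to_numpy() if "failure_12mo" in df.columns else None
            ),
            horizon_months=horizon_months,
        )

    def subset(self, idx: np.ndarray) -> "SurvivalCohort":
        return SurvivalCohort(
            [self.sample_ids[i] for i in np.atleast_1d(idx)],
            self.time_months[idx],
            self.event[idx],
            None,
            self.horizon_months,
        )


@dataclasses.dataclass
class CoxFit:
    """Single-covariate Cox fit summary."""

    beta: float
    se: float
    log_likelihood: float
    c_index: float
    n_events: int
    converged: bool
    capped: bool = False


def _efron_loglik_derivs(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Efron-corrected partial log-likelihood and first two derivatives."""
    eta = beta * x
    exp_eta = np.exp(eta)
    ll = 0.0
    d1 = 0.0
    d2 = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(deaths.sum())
        s0_r = exp_eta[at_risk].sum()
        s1_r = (exp_eta[at_risk] * x[at_risk]).sum()
        s2_r = (exp_eta[at_risk] * x[at_risk] ** 2).sum()
        s0_d = exp_eta[deaths].sum()
        s1_d = (exp_eta[deaths] * x[deaths]).sum()
        s2_d = (exp_eta[deaths] * x[deaths] ** 2).sum()
        ll += eta[deaths].sum()
        d1 += x[deaths].sum()
        for ell in range(d):
            f = ell / d
            s0 = s0_r - f * s0_d
            s1 = s1_r - f * s1_d
            s2 = s2_r - f * s2_d
            ll -= np.log(s0)
            d1 -= s1 / s0
            d2 -= s2 / s0 - (s1 / s0) ** 2
    return ll, d1, d2


def cox_fit(
    covariate: np.ndarray,
    cohort: SurvivalCohort,
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson fit of a single-covariate Cox model.

    ``ties`` is "efron" (default) or "breslow".  A monotone likelihood
    (perfect separation) is reported as a capped beta with a warning rather
    than an error.
    """
    x = np.asarray(covariate, dtype=np.float64)
    if x.shape != (len(cohort),):
        raise ValueError("covariate must align with the cohort")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; no information for a Cox fit")
    n_events = int(cohort.event.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit, got {n_events}")
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie handling {ties!r}")

    time, event = cohort.time_months, cohort.event
    if ties == "breslow":
        deriv = _breslow_loglik_derivs
    else:
        deriv = _efron_loglik_derivs

    beta = 0.0
    converged = False
    capped = False
    ll = np.nan
    for _ in range(max_iter):
        ll, d1, d2 = deriv(beta, x, time, event)
        if d2 >= 0:  # flat/degenerate curvature
            break
        step = -d1 / d2
        beta_new = beta + np.clip(step, -2.0, 2.0)  # damped for stability
        if abs(beta_new) > _BETA_CAP:
            beta = float(np.sign(beta_new) * _BETA_CAP)
            capped = True
            warnings.warn(
                "monotone partial likelihood (perfect separation); beta capped",
                stacklevel=2,
            )
            ll, d1, d2 = deriv(beta, x, time, event)
            break
        if abs(beta_new - beta) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    ll, _, d2 = deriv(beta, x, time, event)
    se = float(np.sqrt(-1.0 / d2)) if d2 < 0 else np.inf
    return CoxFit(
        beta=float(beta),
        se=se,
        log_likelihood=float(ll),
        c_index=c_index(x, cohort),
        n_events=n_events,
        converged=converged,
        capped=capped,
    )


def _breslow_loglik_derivs(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    eta = beta * x
    exp_eta = np.exp(eta)
    ll = d1 = d2 = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        at_risk = time >= t
        d = int(deaths.sum())
        s0 = exp_eta[at_risk].sum()
        s1 = (exp_eta[at_risk] * x[at_risk]).sum()
        s2 = (exp_eta[at_risk] * x[at_risk] ** 2).sum()
        ll += eta[deaths].sum() - d * np.log(s0)
        d1 += x[deaths].sum() - d * s1 / s0
        d2 -= d * (s2 / s0 - (s1 / s0) ** 2)
    return ll, d1, d2


def c_index(scores: np.ndarray, cohort: SurvivalCohort) -> float:
    """Harrell's concordance index.

    Over comparable pairs (i, j) with t_i < t_j and event_i = 1: concordant
    when the shorter-surviving subject has the higher score; score ties
    count 0.5.  Pairs where the earlier time is censored are not comparable.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = cohort.time_months
    e = cohort.event
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(usable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs for the concordance index")
    si, sj = np.broadcast_arrays(s[:, None], s[None, :])
    concordant = (si > sj)[usable].sum() + 0.5 * (si == sj)[usable].sum()
    return float(concordant / n_pairs)


@dataclasses.dataclass
class ComponentSelection:
    """Outcome of per-component Cox screening.

    ``sign`` is +1, or -1 when the selected component was flipped so that a
    higher score means higher risk; the risk score of a sample is
    ``sign * z[selected]``.
    """

    selected: int
    fits: list[CoxFit]
    sign: int
    low_signal: bool

    @property
    def sign_flipped(self) -> bool:
        return self.sign == -1

    def risk_scores(self, z: np.ndarray) -> np.ndarray:
        """Oriented risk score for a (k x N) z-score matrix."""
        return self.sign * np.asarray(z)[self.selected]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(len(self.fits)),
                "beta": [f.beta for f in self.fits],
                "se": [f.se for f in self.fits],
                "c_index": [f.c_index for f in self.fits],
            }
        )


def select_component(
    scores: ComponentScores, cohort: SurvivalCohort, ties: str = "efron"
) -> ComponentSelection:
    """Fit one Cox model per z-scored component row; pick the highest C-index.

    Ties break toward the smaller component index.  If the winner's C-index
    is below 0.5 its sign is flipped (recorded) so that a higher score means
    higher risk; a winner below 0.6 raises the low-signal flag.
    """
    k = scores.z.shape[0]
    if k < 2:
        raise ValueError("need at least 2 components to select among")
    fits = [cox_fit(scores.z[i], cohort, ties=ties) for i in range(k)]
    cs = np.array([f.c_index for f in fits])
    selected = int(np.argmax(cs))  # argmax returns the first max: smaller index
    sign = 1
    if fits[selected].c_index < 0.5:
        sign = -1
        fits[selected] = cox_fit(-scores.z[selected], cohort, ties=ties)
        warnings.warn("selected component sign-flipped so higher score = higher risk",
                      stacklevel=2)
    low_signal = fits[selected].c_index < 0.6
    if low_signal:
        warnings.warn(
            f"selected component C-index {fits[selected].c_index:.3f} < 0.6; "
            "weak prognostic signal",
            stacklevel=2,
        )
    return ComponentSelection(
        selected=selected, fits=fits, sign=sign, low_signal=low_signal
    )


def breslow_cumulative_hazard(
    beta: float, covariate: np.ndarray, cohort: SurvivalCohort
) -> tuple[np.ndarray, np.ndarray]:
    """Breslow estimate of the baseline cumulative hazard.

    Returns (event times, H0 at those times); H0(t) = sum over event times
    t_k <= t of d_k / sum_{risk set} exp(beta x).
    """
    x = np.asarray(covariate, dtype=np.float64)
    exp_eta = np.exp(beta * x)
    times = np.unique(cohort.time_months[cohort.event == 1])
    increments = np.array(
        [
            ((cohort.time_months == t) & (cohort.event == 1)).sum()
            / exp_eta[cohort.time_months >= t].sum()
            for t in times
        ]
    )
    return times, np.cumsum(increments)


def predicted_failure_risk(
    beta: float, covariate: np.ndarray, cohort: SurvivalCohort, horizon: float
) -> np.ndarray:
    """Model-based probability of failure by ``horizon`` months per subject.

    risk_i = 1 - exp(-H0(horizon) * exp(beta x_i)) with the Breslow baseline.
    """
    times, h0 = breslow_cumulative_hazard(beta, covariate, cohort)
    h0_at = float(h0[times <= horizon][-1]) if (times <= horizon).any() else 0.0
    x = np.asarray(covariate, dtype=np.float64)
    return 1.0 - np.exp(-h0_at * np.exp(beta * x))
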