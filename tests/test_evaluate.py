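"""ROC/Youden/confusion, Kaplan-Meier/log-rank, calibration, net benefit, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radionmf.evaluate import (
    calibration_curve,
    confusion_at,
    decision_curve,
    icc,
    km_estimate,
    logrank,
    roc_auc,
    youden_cutoff,
)
from radionmf.survival import SurvivalCohort


def _cohort(times, events):
    n = len(times)
    return SurvivalCohort([f"s{i}" for i in range(n)], np.asarray(times, float),
                          np.asarray(events))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([3, 3, 3, 3], [0, 1, 0, 1]) == 0.5

    def test_matches_sklearn(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        from sklearn.metrics import roc_auc_score

        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_matches_brute_force_pair_counting(self, rng):
        scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(np.exp(scores), labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])


class TestYouden:
    def test_two_point_example(self):
        cutoff, j = youden_cutoff([0.1, 0.9], [0, 1])
        assert cutoff == 0.9 and j == 1.0

    def test_null_labels_give_small_j(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        _, j = youden_cutoff(scores, labels)
        assert j < 0.3

    def test_matches_exhaustive_threshold_scan(self, rng):
        scores = rng.choice(np.round(rng.normal(size=10), 2), size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        best_j, best_cut = -np.inf, None
        for cut in sorted(set(scores)):
            called = scores >= cut
            sens = (called & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~called & (labels == 0)).sum() / (labels == 0).sum()
            j = sens + spec - 1
            if j > best_j:
                best_j, best_cut = j, cut
        cutoff, j = youden_cutoff(scores, labels)
        assert j == pytest.approx(best_j, abs=1e-12)
        assert cutoff == best_cut


class TestConfusion:
    def test_cohort_counts_reproduce_reported_operating_points(self):
        """Training-style counts 9/12 and 60/92 give sens .75 / spec .65;
        validation-style counts 8/11 and 9/13 give .73 / .69 (rounded)."""
        for (tp, pos, tn, neg, sens, spec) in [
            (9, 12, 60, 92, 0.75, 0.65),
            (8, 11, 9, 13, 0.73, 0.69),
        ]:
            labels = np.r_[np.ones(pos), np.zeros(neg)]
            scores = np.r_[np.ones(tp), np.zeros(pos - tp),
                           np.ones(neg - tn), np.zeros(tn)]
            conf = confusion_at(scores, labels, cutoff=0.5)
            assert conf.tp == tp and conf.tn == tn
            assert round(conf.sensitivity, 2) == sens
            assert round(conf.specificity, 2) == spec

    def test_cutoff_below_all_scores(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        conf = confusion_at(scores, labels, scores.min() - 1)
        assert conf.sensitivity == 1.0 if labels.sum() else True
        assert conf.fp == (labels == 0).sum() and conf.tn == 0

    @given(st.integers(0, 2**31 - 1), st.floats(-3, 3))
    @settings(max_examples=25, deadline=None)
    def test_confusion_identities_hold_for_any_cutoff(self, seed, cutoff):
        r = np.random.default_rng(seed)
        scores = r.normal(size=30)
        labels = r.integers(0, 2, 30)
        conf = confusion_at(scores, labels, cutoff)
        assert conf.tp + conf.fn == (labels == 1).sum()
        assert conf.tn + conf.fp == (labels == 0).sum()
        if conf.tp + conf.fn:
            assert conf.sensitivity == conf.tp / (conf.tp + conf.fn)
        if conf.tn + conf.fp:
            assert conf.specificity == conf.tn / (conf.tn + conf.fp)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 1, 1])
        km = km_estimate(cohort)[0]
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2.0

    def test_all_censored_flat_at_one(self):
        cohort = _cohort([5, 6, 7], [0, 0, 0])
        km = km_estimate(cohort)[0]
        assert km.at(100.0) == 1.0
        assert km.median is None

    def test_textbook_data_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        times = [6, 6, 6, 6, 7, 9, 10, 10, 11, 13]
        events = [1, 1, 1, 0, 1, 0, 1, 0, 0, 1]
        km = km_estimate(_cohort(times, events))[0]
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                kmf.survival_function_at_times(t).iloc[0], abs=1e-10
            )


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        times = np.array([3, 5, 7, 9, 3, 5, 7, 9], dtype=float)
        events = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        stat, p = logrank(_cohort(times, events), groups)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_death_time_matches_hypergeometric_closed_form(self):
        # one death at t=2 in group 1; risk sets: n=4, n1=2
        times = [2.0, 5.0, 5.0, 5.0]
        events = [1, 0, 0, 0]
        groups = np.array([1, 1, 0, 0])
        stat, _ = logrank(_cohort(times, events), groups)
        # O-E = 1 - 2/4; Var = 1*(2/4)*(1-2/4)*(4-1)/(4-1) = 0.25
        assert stat == pytest.approx((1 - 0.5) ** 2 / 0.25, abs=1e-12)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        times = rng.exponential(10, 40) + 0.1
        events = rng.integers(0, 2, 40)
        events[:4] = 1
        groups = rng.integers(0, 2, 40)
        groups[:2], groups[2:4] = 0, 1
        stat, p = logrank(_cohort(times, events), groups)
        ref = logrank_test(times[groups == 0], times[groups == 1],
                           events[groups == 0], events[groups == 1])
        assert stat == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_detects_strongly_separated_hazards(self):
        """HR 5 at n=100: significant at p < .005 in nearly all replicates."""
        hits = 0
        n_rep = 20
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            groups = np.r_[np.zeros(50, int), np.ones(50, int)]
            lam = np.where(groups == 1, 0.25, 0.05)
            t = r.exponential(1.0 / lam)
            event = (t <= 20).astype(int)
            t = np.minimum(t, 20)
            _, p = logrank(_cohort(t, event), groups)
            hits += p < 0.005
        assert hits >= int(0.95 * n_rep)


class TestCalibration:
    def test_constant_risk_single_bin_recovers_event_rate(self):
        cohort = _cohort([2, 4, 14, 15, 16, 18], [1, 1, 0, 0, 0, 0])
        pts = calibration_curve(np.full(6, 0.3), cohort, horizon_months=12, n_bins=3)
        assert len(pts) == 1
        assert pts[0][0] == pytest.approx(0.3)
        assert pts[0][1] == pytest.approx(2 / 6)  # no censoring before horizon

    def test_single_bin_requested(self, rng):
        times = rng.exponential(20, 40) + 0.1
        events = (times < 24).astype(int)
        times = np.minimum(times, 24)
        cohort = _cohort(times, events)
        risks = rng.uniform(0, 1, 40)
        pts = calibration_curve(risks, cohort, 12, n_bins=1)
        assert len(pts) == 1
        assert pts[0][0] == pytest.approx(risks.mean())

    def test_well_calibrated_model_tracks_diagonal(self):
        """Risks generated from the true model land near the diagonal."""
        r = np.random.default_rng(3)
        n = 600
        z = r.standard_normal(n)
        lam = 0.02 * np.exp(0.9 * z)
        t = r.exponential(1.0 / lam)
        event = (t <= 30).astype(int)
        time = np.minimum(t, 30)
        cohort = _cohort(np.maximum(time, 1e-3), event)
        true_risk = 1.0 - np.exp(-12.0 * lam)
        pts = calibration_curve(true_risk, cohort, horizon_months=12, n_bins=3)
        for predicted, observed in pts:
            se = np.sqrt(max(predicted * (1 - predicted), 0.01) / (n / 3))
            assert abs(predicted - observed) < 4 * se


class TestDecisionCurve:
    def test_hand_computed_net_benefit(self, rng):
        risks = rng.uniform(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        out = decision_curve(risks, labels, np.array([0.2]))
        called = risks >= 0.2
        tp = (called & (labels == 1)).sum()
        fp = (called & (labels == 0)).sum()
        assert out["net_benefit"][0] == pytest.approx(tp / 50 - fp / 50 * 0.25)

    def test_treat_none_is_zero_and_treat_all_tends_to_prevalence(self, rng):
        labels = rng.integers(0, 2, 60)
        out = decision_curve(rng.uniform(0, 1, 60), labels,
                             np.array([0.001, 0.5]))
        assert np.allclose(out["treat_none"], 0.0)
        assert out["treat_all"][0] == pytest.approx((labels == 1).mean(), abs=2e-3)

    def test_unit_threshold_excluded(self, rng):
        out = decision_curve(rng.uniform(0, 1, 10), rng.integers(0, 2, 10),
                             np.array([0.5, 1.0]))
        assert 1.0 not in out["thresholds"]


class TestICC:
    def test_identical_repeat_measurement_gives_one(self, rng):
        x = rng.normal(10, 3, size=12)
        assert icc(np.column_stack([x, x])) == pytest.approx(1.0)

    def test_matches_pingouin_two_way_absolute_single(self, rng):
        import pandas as pd
        import pingouin as pg

        Y = rng.normal(50, 10, size=(10, 2)) + rng.normal(0, 2, size=(10, 2))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 2),
            "rater": np.tile([0, 1], 10),
            "score": Y.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        two_way_absolute = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        ref_icc2 = ref.loc[two_way_absolute, "ICC"].iloc[0]
        assert icc(Y) == pytest.approx(ref_icc2, abs=1e-8)

    def test_independent_measurements_near_zero_over_replicates(self):
        vals = [icc(np.random.default_rng(s).normal(size=(20, 2)))
                for s in range(40)]
        assert abs(np.mean(vals)) < 0.1

    def test_zero_between_subject_variance_warns_and_returns_zero(self):
        Y = np.tile([[1.0, 2.0]], (5, 1))
        with pytest.warns(UserWarning, match="between-subject"):
            assert icc(Y) == 0.0
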