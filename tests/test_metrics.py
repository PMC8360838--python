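"""ROC analysis, operating points, agreement statistics, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import LogisticRegression

from fastegm import (CvPlan, accuracy_from_rates, cohen_kappa, cross_validate,
                     f1_from_ppv_sensitivity, metrics_at_threshold,
                     patient_folds, roc_auc, threshold_at_sensitivity)


def brute_force_auc(scores, labels):
    """Pair counting: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], n_boot=50)
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0.5] * 10, [0] * 5 + [1] * 5, n_boot=50)
        assert auc == 0.5

    def test_worked_pair_count(self):
        # 4 positive-negative pairs, 3 correctly ranked -> 0.75
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], n_boot=50)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_ci_is_seeded_and_ordered(self):
        rng = np.random.default_rng(0)
        s = rng.random(60)
        y = (s + rng.normal(0, 0.3, 60) > 0.5).astype(int)
        a1 = roc_auc(s, y, n_boot=200, seed=5)
        a2 = roc_auc(s, y, n_boot=200, seed=5)
        assert a1 == a2
        lo, hi = a1[1]
        assert lo <= a1[0] <= hi

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_auc_equals_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 200))
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, _ = roc_auc(scores, labels, n_boot=0)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestThresholdAtSensitivity:
    def test_perfect_classifier_at_target(self):
        scores = np.array([0.1, 0.2, 0.3, 0.8, 0.85, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        thr = threshold_at_sensitivity(scores, labels, 0.90)
        rep = metrics_at_threshold(scores, labels, thr)
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_ten_positives_admit_nine_or_ten(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.random(10), rng.random(10) * 0.5])
        labels = np.array([1] * 10 + [0] * 10)
        thr = threshold_at_sensitivity(scores, labels, 0.90)
        admitted = np.sum((scores >= thr) & (labels == 1))
        assert admitted in (9, 10)

    def test_target_one_returns_minimum_positive_score(self):
        scores = np.array([0.4, 0.6, 0.1, 0.9])
        labels = np.array([0, 1, 0, 1])
        assert threshold_at_sensitivity(scores, labels, 1.0) == 0.6

    def test_all_positive_degenerates_to_min_score(self):
        assert threshold_at_sensitivity([0.3, 0.7], [1, 1], 0.9) == 0.3

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from([0.85, 0.90, 0.95]))
    def test_achieved_sensitivity_minimal_above_target(self, seed, target):
        """Exhaustive sweep oracle: the returned threshold achieves the
        smallest sensitivity >= target over all possible thresholds."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if labels.sum() == 0:
            labels[0] = 1
        if labels.sum() == n:
            labels[-1] = 0
        thr = threshold_at_sensitivity(scores, labels, target)
        pos = scores[labels == 1]
        achieved = np.mean(pos >= thr)
        assert achieved >= target
        feasible = [np.mean(pos >= t) for t in np.unique(scores)
                    if np.mean(pos >= t) >= target]
        assert achieved == min(feasible)


class TestMetricsReport:
    def test_all_correct(self):
        rep = metrics_at_threshold([0.1, 0.9], [0, 1], 0.5)
        for field in ("sensitivity", "specificity", "ppv", "npv", "f1", "accuracy"):
            assert getattr(rep, field) == 1.0

    def test_f1_harmonic_mean_identity_on_reported_rates(self):
        # PPV 42.3% with sensitivity 78% -> F1 0.549
        assert round(f1_from_ppv_sensitivity(0.423, 0.78), 3) == 0.549

    def test_accuracy_prevalence_identity_on_reported_rates(self):
        # prevalence 9.2%, sensitivity 78%, specificity 87.3% -> 86.4%
        assert round(100 * accuracy_from_rates(0.092, 0.78, 0.873), 1) == 86.4

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_identities_hold_exactly_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        rep = metrics_at_threshold(scores, labels, 0.5)
        if rep.ppv > 0 and rep.sensitivity > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity))
        assert rep.accuracy == pytest.approx(
            rep.prevalence * rep.sensitivity
            + (1 - rep.prevalence) * rep.specificity)
        assert rep.tp + rep.fp + rep.tn + rep.fn == n

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            metrics_at_threshold([], [], 0.5)


class TestCohenKappa:
    def test_identical_labels(self):
        assert cohen_kappa([0, 1, 1, 0], [0, 1, 1, 0]) == 1.0

    def test_hand_computed_table(self):
        # TP=40, FP=10, FN=10, TN=40: p_o = 0.8, p_e = 0.5 -> kappa 0.6
        a = [1] * 40 + [0] * 10 + [1] * 10 + [0] * 40
        b = [1] * 40 + [1] * 10 + [0] * 10 + [0] * 40
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.integers(0, 2, 50)
            b = rng.integers(0, 2, 50)
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_constant_identical_raters(self):
        assert cohen_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohen_kappa([0, 1], [0, 1, 1])


class _SkEstimator:
    """Tiny sklearn-wrapped stand-in so cross-validation runs fast."""

    def __init__(self, seed=0):
        self.est = LogisticRegression(max_iter=200, random_state=seed)

    def fit(self, X, y):
        self.est.fit(X, y)
        return self

    def decision_function(self, X):
        return self.est.decision_function(X)


def _toy_cv_data(n_patients=6, per_patient=30, seed=0):
    rng = np.random.default_rng(seed)
    X, y, g = [], [], []
    for p in range(n_patients):
        xs = rng.normal(size=(per_patient, 5))
        ys = (xs[:, 0] + rng.normal(0, 0.5, per_patient) > 0).astype(int)
        X.append(xs)
        y.append(ys)
        g += [f"pt{p}"] * per_patient
    return np.vstack(X), np.concatenate(y), np.array(g)


class TestCrossValidation:
    def test_folds_partition_patients(self):
        g = np.repeat([f"pt{i}" for i in range(6)], 10)
        folds = patient_folds(g, 3, seed=0)
        test_sets = [set(g[te]) for _, te in folds]
        assert set().union(*test_sets) == set(g)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (test_sets[i] & test_sets[j])
        for tr, te in folds:
            assert not (set(g[tr]) & set(g[te]))

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError):
            patient_folds(np.array(["a", "b"]), 3)

    def test_five_seeds_give_distinct_assignments(self):
        X, y, g = _toy_cv_data()
        plan = CvPlan(n_folds=3, n_seeds=5)
        table, summary = cross_validate(X, y, g, lambda s: _SkEstimator(s),
                                        plan, seed=1)
        assignments = summary["fold_assignments"]
        assert len({a["seed"] for a in assignments}) == 5
        assert len(table) == 15
        assert "auc_mean" in summary and "auc_sd" in summary

    def test_subsample_fractions_reported_and_nested(self):
        X, y, g = _toy_cv_data(n_patients=8)
        plan = CvPlan(n_folds=2, n_seeds=1, subsample_fractions=[0.5, 1.0])
        table, summary = cross_validate(X, y, g, lambda s: _SkEstimator(s),
                                        plan, seed=2)
        assert set(table["fraction"]) == {0.5, 1.0}
        assert "auc_mean_frac0.5" in summary
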