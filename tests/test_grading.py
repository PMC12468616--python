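"""Unit tests for WHO rules, combinations, CV protocol and classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nengrade.grading import (
    ClassifierConfig,
    balanced_accuracy,
    combined_grade,
    naive_combination_1,
    naive_combination_2,
    patient_grade,
    stratified_folds,
    train_histogram_classifier,
    who_grade_ki67,
    who_grade_mitotic,
)

grades_lists = st.lists(st.integers(1, 3), min_size=1, max_size=20)


class TestWHORules:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, 1), (1, 1), (1.9, 1), (2, 2), (10, 2), (20, 2), (20.5, 3), (21, 3), (100, 3)],
    )
    def test_mitotic_thresholds(self, count, expected):
        assert who_grade_mitotic(count) == expected

    @pytest.mark.parametrize(
        "pct,expected",
        [(0, 1), (2.9, 1), (3, 2), (10, 2), (20, 2), (20.1, 3), (25, 3), (100, 3)],
    )
    def test_ki67_thresholds(self, pct, expected):
        assert who_grade_ki67(pct) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            who_grade_mitotic(-1)
        with pytest.raises(ValueError):
            who_grade_ki67(101)

    def test_monotone_non_decreasing(self):
        counts = np.linspace(0, 60, 200)
        grades = [who_grade_mitotic(c) for c in counts]
        assert all(b >= a for a, b in zip(grades, grades[1:]))
        pcts = np.linspace(0, 100, 200)
        grades = [who_grade_ki67(p) for p in pcts]
        assert all(b >= a for a, b in zip(grades, grades[1:]))


class TestCombination:
    @pytest.mark.parametrize("grades,expected", [([1, 3], 3), ([2], 2), ([1, 2, 1], 2)])
    def test_combined_examples(self, grades, expected):
        assert combined_grade(grades) == expected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(grades_lists)
    def test_combined_is_max_and_commutative(self, grades):
        assert combined_grade(grades) == max(grades)
        assert combined_grade(list(reversed(grades))) == combined_grade(grades)
        assert combined_grade([combined_grade(grades)]) == combined_grade(grades)

    @pytest.mark.parametrize(
        "hne,pct,expected", [(1, 25, 3), (3, 1, 3), (2, 10, 2), (1, 2.9, 1)]
    )
    def test_naive_combination_1(self, hne, pct, expected):
        assert naive_combination_1(hne, pct) == expected

    @pytest.mark.parametrize("a,b,expected", [(1, 2, 2), (3, 1, 3), (2, 2, 2)])
    def test_naive_combination_2(self, a, b, expected):
        assert naive_combination_2(a, b) == expected

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(grades_lists)
    def test_patient_grade_dominates_slides(self, slide_grades):
        pg = patient_grade(slide_grades)
        assert pg == max(slide_grades)
        assert all(pg >= g for g in slide_grades)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combined_grade([])
        with pytest.raises(ValueError):
            patient_grade([])


class TestStratifiedFolds:
    def test_exact_stratification_nine_patients(self):
        patients = [(f"p{i}", 1 + i % 3) for i in range(9)]
        split = stratified_folds(patients, k=3, seed=0)
        for fold in range(3):
            grades = sorted(
                g for (pid, g) in patients if split.fold_of_patient[pid] == fold
            )
            assert grades == [1, 2, 3]

    def test_deterministic_given_seed(self):
        patients = [(f"p{i}", 1 + i % 3) for i in range(30)]
        a = stratified_folds(patients, k=3, seed=5)
        b = stratified_folds(patients, k=3, seed=5)
        assert a.fold_of_patient == b.fold_of_patient
        assert a.role_of_patient == b.role_of_patient

    def test_cohort_scale_proportions_within_one_patient(self):
        # grade mix echoing a 186-patient resection cohort (109/56/21)
        patients = (
            [(f"g1_{i}", 1) for i in range(109)]
            + [(f"g2_{i}", 2) for i in range(56)]
            + [(f"g3_{i}", 3) for i in range(21)]
        )
        split = stratified_folds(patients, k=3, seed=1)
        for fold in range(3):
            for grade, total in ((1, 109), (2, 56), (3, 21)):
                n = sum(
                    1
                    for pid, g in patients
                    if g == grade and split.fold_of_patient[pid] == fold
                )
                assert abs(n - total / 3) <= 1

    def test_roles_split_folds_about_equally(self):
        patients = [(f"p{i}", 1 + i % 3) for i in range(60)]
        split = stratified_folds(patients, k=3, seed=2)
        for fold in range(3):
            roles = [
                split.role_of_patient[pid]
                for pid, _ in patients
                if split.fold_of_patient[pid] == fold
            ]
            assert abs(roles.count("test") - roles.count("val")) <= 2

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds([("a", 1), ("b", 2), ("c", 3)], k=3)


class TestBalancedAccuracy:
    def test_perfect_is_one(self):
        assert balanced_accuracy([1, 2, 3, 3], [1, 2, 3, 3]) == 1.0

    def test_constant_predictor_on_balanced_classes(self):
        assert balanced_accuracy([1, 2, 3], [2, 2, 2]) == pytest.approx(1 / 3)

    def test_hand_computed_confusion(self):
        # recalls: G1 2/3, G2 1/2, G3 1/1 -> mean 0.7222
        y_true = [1, 1, 1, 2, 2, 3]
        y_pred = [1, 1, 2, 2, 3, 3]
        assert balanced_accuracy(y_true, y_pred) == pytest.approx((2 / 3 + 1 / 2 + 1) / 3)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([1, 2], [1])


class TestClassifier:
    @staticmethod
    def _separable(n_per_class=20, seed=0):
        # three disjoint support regions in a 30-dim histogram space
        rng = np.random.default_rng(seed)
        X, y = [], []
        for grade, lo in ((1, 0), (2, 10), (3, 20)):
            for _ in range(n_per_class):
                h = np.zeros(30)
                bins = rng.integers(lo, lo + 10, size=8)
                for b in bins:
                    h[b] += 1
                X.append(h / h.sum())
                y.append(grade)
        return np.array(X), np.array(y)

    @pytest.mark.parametrize("model", ["mlp", "logistic"])
    def test_separable_training_is_perfect(self, model):
        X, y = self._separable()
        clf = train_histogram_classifier(X, y, ClassifierConfig(model=model, seed=0))
        assert balanced_accuracy(y, clf.predict(X)) == 1.0

    def test_reproducible_given_seed(self):
        X, y = self._separable(seed=3)
        cfg = ClassifierConfig(seed=42)
        a = train_histogram_classifier(X, y, cfg).predict(X)
        b = train_histogram_classifier(X, y, cfg).predict(X)
        assert (a == b).all()

    def test_missing_grade_rejected(self):
        X = np.zeros((10, 5))
        y = np.array([1] * 5 + [2] * 5)
        with pytest.raises(ValueError):
            train_histogram_classifier(X, y, ClassifierConfig())
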