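"""WHO grading rules, learned histogram classifiers, combination
strategies and the cross-validation protocol.

The 2019 WHO scheme grades a neuroendocrine neoplasm from two measures:
the mitotic count per 2 mm^2 (G1 < 2, G2 2–20, G3 > 20) and the Ki-67
index in percent (G1 < 3, G2 3–20, G3 > 20).  When the two disagree the
higher grade takes precedence; likewise a patient with several slides
receives the highest slide grade.

Learned grading replaces the rule with a classifier (MLP or logistic
regression) over the slide histogram features.  Two "naive" combination
strategies fuse the H&E route with Ki-67: (1) max of the H&E-classifier
grade and the WHO grade of the Ki-67 hotspot index; (2) max of the H&E
and Ki-67 classifier grades.  Evaluation follows a grade-stratified
3-fold protocol with class weighting, scored by balanced accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .grades import combined_grade, patient_grade, who_grade_ki67, who_grade_mitotic

__all__ = [
    "GradeThresholds",
    "ClassifierConfig",
    "CVSplit",
    "who_grade_mitotic",
    "who_grade_ki67",
    "combined_grade",
    "patient_grade",
    "naive_combination_1",
    "naive_combination_2",
    "train_histogram_classifier",
    "stratified_folds",
    "balanced_accuracy",
    "cross_validate",
]

# Re-exported rule primitives live in .grades to keep this module's
# focus on the learned pipeline.
from .grades import GradeThresholds  # noqa: E402  (re-export)


@dataclass(frozen=True)
class ClassifierConfig:
    """Histogram-classifier settings.

    The MLP is a single hidden layer of rectified units with a softmax
    output — the smallest architecture adequate for 49–150-dimensional
    histogram inputs.  ``class_weighting="inverse_frequency"`` gives each
    grade equal importance regardless of cohort imbalance.
    """

    model: str = "mlp"  # "mlp" | "logistic"
    hidden_units: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 500
    class_weighting: str = "inverse_frequency"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("mlp", "logistic"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "mlp" and self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1 for the MLP")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass(frozen=True)
class CVSplit:
    """Patient-level fold assignment plus test/val roles within the
    held-out fold."""

    fold_of_patient: dict
    role_of_patient: dict
    k: int


def naive_combination_1(hne_nn_grade: int, ki67_hotspot_pct: float) -> int:
    """Max of the H&E-classifier grade and the WHO grade of the Ki-67
    hotspot index."""
    return combined_grade([hne_nn_grade, who_grade_ki67(ki67_hotspot_pct)])


def naive_combination_2(hne_nn_grade: int, ki67_nn_grade: int) -> int:
    """Max of the H&E-classifier and Ki-67-classifier grades."""
    return combined_grade([hne_nn_grade, ki67_nn_grade])


def _inverse_frequency_weights(y: np.ndarray) -> dict[int, float]:
    classes, counts = np.unique(y, return_counts=True)
    raw = y.size / (len(classes) * counts)
    raw = raw / raw.mean()  # normalize to mean 1
    return {int(c): float(w) for c, w in zip(classes, raw)}


def _balanced_oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    # Seeded oversampling to equal class counts: the sampling-based
    # equivalent of inverse-frequency loss weights, for estimators that
    # do not accept class weights.
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    idx_parts = []
    for c, n in zip(classes, counts):
        idx = np.flatnonzero(y == c)
        if n < target:
            extra = rng.choice(idx, size=target - n, replace=True)
            idx = np.concatenate([idx, extra])
        idx_parts.append(idx)
    order = rng.permutation(np.concatenate(idx_parts))
    return X[order], y[order]


def train_histogram_classifier(
    X: np.ndarray,
    y: Sequence[int],
    config: ClassifierConfig | None = None,
):
    """Fit a 3-class grade classifier on histogram features.

    Every grade must be present in the training data.  Training is
    reproducible given ``config.seed``.  Returns a fitted scikit-learn
    estimator exposing ``predict``.
    """
    config = config or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) aligned with y")
    present = set(np.unique(y).tolist())
    if not {1, 2, 3} <= present:
        raise ValueError(f"all three grades must appear in training data, got {sorted(present)}")

    weighted = config.class_weighting == "inverse_frequency"
    if config.model == "logistic":
        clf = LogisticRegression(
            max_iter=max(config.max_epochs, 200),
            class_weight=_inverse_frequency_weights(y) if weighted else None,
            random_state=config.seed,
        )
        clf.fit(X, y)
        return clf

    clf = MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        learning_rate_init=config.learning_rate,
        max_iter=config.max_epochs,
        random_state=config.seed,
    )
    if weighted:
        rng = np.random.default_rng(config.seed)
        X, y = _balanced_oversample(X, y, rng)
    clf.fit(X, y)
    return clf


def stratified_folds(
    patients: Sequence[tuple[object, int]],
    k: int = 3,
    seed: int = 0,
) -> CVSplit:
    """Grade-stratified k-fold assignment of patients.

    Each grade's patients are shuffled (seeded) and dealt round-robin to
    folds, keeping per-fold grade proportions within one patient of the
    global mix.  Within each fold, patients alternate test/val roles
    (grade-wise), so the held-out fold splits ~equally when used.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    by_grade: dict[int, list] = {}
    for pid, grade in patients:
        by_grade.setdefault(int(grade), []).append(pid)
    rng = np.random.default_rng(seed)
    fold_of: dict = {}
    role_of: dict = {}
    role_counter: dict[int, int] = {}
    for grade in sorted(by_grade):
        ids = by_grade[grade]
        if len(ids) < k:
            raise ValueError(f"grade {grade} has fewer than k={k} patients")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        for i, pid in enumerate(ids):
            fold = i % k
            fold_of[pid] = fold
            j = role_counter.get(fold, 0)
            role_of[pid] = "test" if j % 2 == 0 else "val"
            role_counter[fold] = j + 1
    return CVSplit(fold_of_patient=fold_of, role_of_patient=role_of, k=k)


def balanced_accuracy(y_true: Sequence[int], y_pred: Sequence[int]) -> float:
    """Unweighted mean of per-class recall over the classes in y_true."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    recalls = []
    for c in np.unique(y_true):
        sel = y_true == c
        recalls.append(np.mean(y_pred[sel] == c))
    return float(np.mean(recalls))


def cross_validate(
    features: Mapping[object, np.ndarray],
    labels: Mapping[object, int],
    k: int = 3,
    seed: int = 0,
    config: ClassifierConfig | None = None,
) -> dict:
    """Run the grade-stratified k-fold protocol on patient features.

    For each permutation, two folds train and the held-out fold's "test"
    half is scored; the reported metric is the mean test balanced
    accuracy over folds (per-fold values are returned too).
    """
    config = config or ClassifierConfig()
    patients = [(pid, labels[pid]) for pid in features]
    split = stratified_folds(patients, k=k, seed=seed)
    fold_scores = []
    for fold in range(k):
        train_ids = [p for p, f in split.fold_of_patient.items() if f != fold]
        test_ids = [
            p
            for p, f in split.fold_of_patient.items()
            if f == fold and split.role_of_patient[p] == "test"
        ]
        X_train = np.stack([features[p] for p in train_ids])
        y_train = np.array([labels[p] for p in train_ids])
        clf = train_histogram_classifier(X_train, y_train, config)
        X_test = np.stack([features[p] for p in test_ids])
        y_test = np.array([labels[p] for p in test_ids])
        fold_scores.append(balanced_accuracy(y_test, clf.predict(X_test)))
    return {
        "fold_balanced_accuracy": fold_scores,
        "mean_balanced_accuracy": float(np.mean(fold_scores)),
        "split": split,
    }
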