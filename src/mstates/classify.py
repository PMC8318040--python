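"""Cross-validated high/low classification from microstate features.

Folds are built at the trial level — all windows of one trial share a fold —
so temporally adjacent windows can never leak between training and test
sets. Features are standardized with statistics from the training folds
only. Accuracy is (TP + TN) / (TP + TN + FP + FN) on the counts pooled over
folds; per-fold accuracies give the spread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledFeatureSet",
    "CVPlan",
    "ConfusionCounts",
    "EvaluationReport",
    "make_folds",
    "accuracy",
    "evaluate",
    "CLASSIFIERS",
]

log = logging.getLogger(__name__)


@dataclass
class LabeledFeatureSet:
    """Feature matrix with binary labels and trial-level group ids."""

    X: np.ndarray
    y: np.ndarray  # 1 = high, 0 = low
    groups: np.ndarray
    dimension: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.groups = np.asarray(self.groups)
        n = self.X.shape[0]
        if len(self.y) != n or len(self.groups) != n:
            raise ValueError("X, y and groups must agree in length")


@dataclass
class CVPlan:
    k: int
    fold_of_row: np.ndarray
    seed: int


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.TN + other.TN, self.FP + other.FP, self.FN + other.FN
        )


@dataclass
class EvaluationReport:
    per_fold: list[ConfusionCounts]
    pooled: ConfusionCounts
    accuracy: float
    fold_accuracies: list[float]
    classifier: str
    feature_set: str = ""
    classifier_params: dict = field(default_factory=dict)

    @property
    def mean_fold_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_fold_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1)) if len(self.fold_accuracies) > 1 else 0.0


def make_folds(groups, k: int = 5, seed: int = 0, labels=None) -> CVPlan:
    """Deal shuffled trial ids round-robin into k folds.

    When per-group labels are supplied and constant within group, groups are
    dealt per label stratum so each fold sees both classes.
    """
    groups = np.asarray(groups)
    unique = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    if len(unique) < k:
        raise ValueError(f"need at least {k} distinct groups, got {len(unique)}")
    rng = np.random.default_rng(seed)
    fold_of_group = {}
    if labels is not None:
        labels = np.asarray(labels)
        label_of_group = {}
        for g, lab in zip(groups, labels):
            if g in label_of_group and label_of_group[g] != lab:
                label_of_group[g] = None  # mixed label; no stratification
            else:
                label_of_group.setdefault(g, lab)
        strata: dict = {}
        for g in unique:
            strata.setdefault(label_of_group.get(g), []).append(g)
        i = 0
        for _, members in sorted(strata.items(), key=lambda kv: str(kv[0])):
            members = list(members)
            rng.shuffle(members)
            for g in members:
                fold_of_group[g] = i % k
                i += 1
    else:
        shuffled = list(unique)
        rng.shuffle(shuffled)
        for i, g in enumerate(shuffled):
            fold_of_group[g] = i % k
    fold_of_row = np.array([fold_of_group[g] for g in groups])
    return CVPlan(k=k, fold_of_row=fold_of_row, seed=seed)


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("no evaluated rows")
    return (c.TP + c.TN) / c.total


def _svm(seed):
    from sklearn.svm import SVC

    return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)


def _random_forest(seed):
    from sklearn.ensemble import RandomForestClassifier

    return RandomForestClassifier(n_estimators=200, random_state=seed)


def _feed_forward(seed):
    from sklearn.neural_network import MLPClassifier

    return MLPClassifier(hidden_layer_sizes=(64,), max_iter=500, random_state=seed)


CLASSIFIERS = {
    "svm": _svm,
    "support-vector-machine": _svm,
    "random-forest": _random_forest,
    "feed-forward-network": _feed_forward,
    "ann": _feed_forward,
}


def evaluate(
    data: LabeledFeatureSet,
    classifier_spec: str,
    plan: CVPlan,
    backend_seed: int = 0,
) -> EvaluationReport:
    """k-fold cross-validation with training-fold-only standardization.

    Folds whose training part holds a single class are skipped with a
    warning. Label 1 (high) is the positive class.
    """
    if classifier_spec not in CLASSIFIERS:
        raise ValueError(
            f"unknown classifier {classifier_spec!r}; choose from {sorted(CLASSIFIERS)}"
        )
    if len(plan.fold_of_row) != len(data.y):
        raise ValueError("CV plan does not match the dataset")
    from sklearn.preprocessing import StandardScaler

    per_fold: list[ConfusionCounts] = []
    fold_acc: list[float] = []
    for f in range(plan.k):
        test = plan.fold_of_row == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(data.y[train])) < 2:
            log.warning("fold %d has a single training class; skipped", f)
            continue
        scaler = StandardScaler().fit(data.X[train])
        clf = CLASSIFIERS[classifier_spec](backend_seed)
        clf.fit(scaler.transform(data.X[train]), data.y[train])
        pred = clf.predict(scaler.transform(data.X[test]))
        truth = data.y[test]
        c = ConfusionCounts(
            TP=int(np.sum((pred == 1) & (truth == 1))),
            TN=int(np.sum((pred == 0) & (truth == 0))),
            FP=int(np.sum((pred == 1) & (truth == 0))),
            FN=int(np.sum((pred == 0) & (truth == 1))),
        )
        per_fold.append(c)
        fold_acc.append(accuracy(c))
    if not per_fold:
        raise ValueError("no fold could be evaluated")
    pooled = per_fold[0]
    for c in per_fold[1:]:
        pooled = pooled + c
    clf_example = CLASSIFIERS[classifier_spec](backend_seed)
    return EvaluationReport(
        per_fold=per_fold,
        pooled=pooled,
        accuracy=accuracy(pooled),
        fold_accuracies=fold_acc,
        classifier=classifier_spec,
        classifier_params=clf_example.get_params(),
    )
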