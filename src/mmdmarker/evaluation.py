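"""Cross-validated evaluation of a selected gene panel.

Selected genes are judged by how well their expression separates tumor
samples from everything else (normal and NAT pooled as the negative
class) in stratified k-fold cross-validation with a random-forest
classifier, the standard protocol for marker panels.  Four metrics are
reported per fold and as means: recall, F1, accuracy and the Matthews
correlation coefficient

    MCC = (tp·tn - fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),

a balanced summary in [-1, 1] that stays honest under the class
imbalance typical of tumor cohorts.  Pooled-count metrics (computed on
the summed confusion table) are reported alongside the fold means, and
the whole procedure is deterministic given the seed.

Note the genes are assumed to have been selected on the full data set
before cross-validation; the evaluation therefore measures the panel's
separability, not an unbiased estimate of out-of-cohort performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, GroupLabels

__all__ = [
    "ConfusionCounts",
    "CVConfig",
    "CVMetrics",
    "stratified_kfold_indices",
    "compute_metrics",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts; the positive class is tumor."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings: fold count, seed, positive class, and
    classifier hyperparameters (a seeded 100-tree random forest)."""

    k: int = 10
    seed: int = 0
    positive_class: str = "tumor"
    n_trees: int = 100

    def __post_init__(self):
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")


@dataclass(frozen=True)
class MetricSet:
    recall: float
    f1: float
    accuracy: float
    mcc: float
    degenerate: bool = False


@dataclass(frozen=True)
class CVMetrics:
    """Per-fold metrics plus their means and the pooled-count metrics."""

    per_fold: tuple
    fold_counts: tuple
    recall: float
    f1: float
    accuracy: float
    mcc: float
    pooled: MetricSet = field(default=None)


def stratified_kfold_indices(binary_labels, k: int, seed: int):
    """k disjoint, stratified test-index arrays covering every sample once.

    Per-fold class counts differ from exact proportionality by at most
    one; the same seed reproduces the same folds.
    """
    y = np.asarray(binary_labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples, fewer than k={k} folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(y.size), y)]


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Recall, F1, accuracy and MCC from confusion counts.

    Any metric whose denominator is zero is reported as 0 and the
    result is flagged degenerate rather than raising.
    """
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    degenerate = False

    def guarded(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    recall = guarded(tp, tp + fn)
    precision = guarded(tp, tp + fp)
    f1 = guarded(2 * precision * recall, precision + recall)
    accuracy = guarded(tp + tn, counts.total)
    mcc_den = sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = guarded(tp * tn - fp * fn, mcc_den)
    return MetricSet(recall, f1, accuracy, mcc, degenerate)


def cross_validate(
    matrix: ExpressionMatrix, labels: GroupLabels, config: CVConfig = CVConfig()
) -> CVMetrics:
    """Stratified k-fold CV of positive-class-vs-rest classification.

    ``matrix`` should already be restricted to the selected genes
    (samples are feature rows, genes are features).  Every sample is
    predicted exactly once; per-fold confusion counts, per-fold
    metrics, their means, and the pooled-count metrics are returned.
    """
    if matrix.n_genes == 0:
        raise ValueError("the selected gene set is empty")
    y = np.array(
        [labels.group_of(s) == config.positive_class for s in matrix.sample_ids]
    )
    if y.all() or not y.any():
        raise ValueError(
            f"all samples are on one side of {config.positive_class!r}-vs-rest"
        )
    X = matrix.values.T  # samples × genes
    folds = stratified_kfold_indices(y, config.k, config.seed)

    per_fold, fold_counts = [], []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold_id, test_idx in enumerate(folds):
        train_mask = np.ones(y.size, dtype=bool)
        train_mask[test_idx] = False
        y_train = y[train_mask]
        if y_train.all() or not y_train.any():
            raise ValueError(
                f"fold {fold_id} trains on a single class; "
                "use a smaller k or more data"
            )
        clf = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed
        )
        clf.fit(X[train_mask], y_train)
        pred = clf.predict(X[test_idx])
        truth = y[test_idx]
        counts = ConfusionCounts(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
            tn=int((~pred & ~truth).sum()),
        )
        fold_counts.append(counts)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts

    return CVMetrics(
        per_fold=tuple(per_fold),
        fold_counts=tuple(fold_counts),
        recall=float(np.mean([m.recall for m in per_fold])),
        f1=float(np.mean([m.f1 for m in per_fold])),
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        mcc=float(np.mean([m.mcc for m in per_fold])),
        pooled=compute_metrics(pooled),
    )
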