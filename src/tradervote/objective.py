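"""SVM-accuracy fitness for feature subsets.

A candidate subset is scored by the mean-based multiclass accuracy
(sum_i TP_i / N over a pooled confusion matrix) of an SVM trained on those
feature columns under internal stratified cross-validation. The accuracy is
the subset's worthiness/fitness during the search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datatable import DataTable


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def class_count(self) -> int:
        return self.counts.shape[0]


def multiclass_accuracy(cm: ConfusionMatrix) -> float:
    """Mean-based multiclass accuracy: sum of per-class true positives / N."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.N)


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified partition into ``k`` folds.

    Per-class counts across folds differ by at most one; identical seeds
    yield identical folds.
    """
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"{k} folds exceed the smallest class count ({counts.min()})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(labels), labels)]


@dataclass
class ObjectiveConfig:
    """SVM fitness settings.

    ``inner_folds=1`` is a leak-prone compatibility mode scoring
    resubstitution accuracy instead of cross-validated accuracy.
    """

    kernel: str = "rbf"
    c_svm: float = 1.0
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.c_svm <= 0:
            raise ValueError("regularization parameter must be positive")
        if self.inner_folds < 1:
            raise ValueError("inner_folds must be >= 1")


def _make_svm(config: ObjectiveConfig) -> SVC:
    return SVC(kernel=config.kernel, C=config.c_svm, gamma="scale")


def subset_columns(subset: Union[Sequence[int], "object"], n_features: int,
                   ) -> np.ndarray:
    """0-based column array from a CandidateSolution or 1-based index iterable."""
    indices = getattr(subset, "indices", subset)
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise ValueError("empty feature subset")
    if idx.min() < 1 or idx.max() > n_features:
        raise ValueError("subset indices out of range")
    if len(np.unique(idx)) != idx.size:
        raise ValueError("subset indices must be distinct")
    return np.sort(idx) - 1


def svm_fitness(table: DataTable, subset, config: ObjectiveConfig) -> float:
    """Accuracy of an SVM restricted to ``subset``, in [0, 1].

    Runs internal stratified k-fold CV, pools the per-fold predictions into
    one confusion matrix and returns its mean-based multiclass accuracy.
    Deterministic given the config seed; invariant to index order within
    the subset.
    """
    if table.missing_mask.any():
        raise ValueError("fitness requires a preprocessed (complete) table")
    cols = subset_columns(subset, table.n_features)
    X = table.values[:, cols]
    y = table.labels
    C = table.class_count
    if config.inner_folds == 1:
        model = _make_svm(config).fit(X, y)
        y_pred = model.predict(X)
        y_true = y
    else:
        preds, trues = [], []
        for test in stratified_folds(y, config.inner_folds, config.seed):
            train = np.setdiff1d(np.arange(len(y)), test)
            model = _make_svm(config).fit(X[train], y[train])
            preds.append(model.predict(X[test]))
            trues.append(y[test])
        y_pred = np.concatenate(preds)
        y_true = np.concatenate(trues)
    cm = ConfusionMatrix(_sk_confusion(y_true, y_pred, labels=np.arange(C)))
    return multiclass_accuracy(cm)


class SubsetObjective:
    """Callable fitness with call accounting and a memoization cache.

    Every invocation counts as one objective call — including cache hits —
    so budget-parity comparisons between optimizers stay exact while
    repeated subsets cost no extra wall-clock.
    """

    def __init__(self, table: DataTable, config: ObjectiveConfig | None = None):
        self.table = table
        self.config = config or ObjectiveConfig()
        self.calls = 0
        self._cache: dict[frozenset, float] = {}

    def __call__(self, subset) -> float:
        self.calls += 1
        key = frozenset(int(v) for v in getattr(subset, "indices", subset))
        if key not in self._cache:
            self._cache[key] = svm_fitness(self.table, subset, self.config)
        return self._cache[key]

    @property
    def unique_evaluations(self) -> int:
        return len(self._cache)
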