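"""Outer cross-validation harness and reported statistics.

Covers the full reporting stack: confusion-matrix-derived ACC/PRE/SEN/SPC/F
with mean-based (macro one-vs-rest) multiclass extension, macro-averaged
ROC and PR curves with trapezoidal AUC, the Wilcoxon rank-sum comparison of
optimizer run sets, boxplot/convergence summaries of repeated runs, and the
nested fivefold cross-validated pipeline (preprocess -> select -> vote).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc

from ._seeds import derive_seed
from .datatable import DataTable
from .objective import (ConfusionMatrix, ObjectiveConfig, SubsetObjective,
                        multiclass_accuracy, stratified_folds)
from .preprocess import apply_min_max, impute_missing, min_max_normalize
from .trader import (SearchResult, TraderConfig, random_search_baseline,
                     trader_search)
from .voting import EnsembleModel, build_ensemble, vote_predict, vote_scores


def confusion(y_true: Sequence[int], y_pred: Sequence[int], C: int,
              ) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for y in (y_true, y_pred):
        if y.min() < 0 or y.max() >= C:
            raise ValueError("label out of range")
    return ConfusionMatrix(_sk_confusion(y_true, y_pred, labels=np.arange(C)))


@dataclass
class MetricsReport:
    """ACC/PRE/SEN/SPC/F plus the per-class one-vs-rest breakdown."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f_score: float
    confusion: ConfusionMatrix
    per_class: dict[str, np.ndarray]
    average: str = "macro"

    def to_dict(self) -> dict:
        return {
            "average": self.average,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f_score": self.f_score,
            "per_class": {k: [float(x) for x in v]
                          for k, v in self.per_class.items()},
            "confusion": self.confusion.counts.tolist(),
        }

    def summary(self) -> str:
        return ("ACC={:.4f} PRE={:.4f} SEN={:.4f} SPC={:.4f} F={:.4f}"
                .format(self.accuracy, self.precision, self.sensitivity,
                        self.specificity, self.f_score))


def metrics_report(cm: ConfusionMatrix, average: str = "macro",
                   ) -> MetricsReport:
    """Mean-based multiclass metrics from a pooled confusion matrix.

    Per class i (one-vs-rest): PRE_i = TP_i/(TP_i+FP_i), SEN_i =
    TP_i/(TP_i+FN_i), SPC_i = TN_i/(TN_i+FP_i), each 0 when its denominator
    is 0. ``macro`` averages the per-class values unweighted; ``micro``
    pools the binary counts across classes. F is the harmonic mean of the
    averaged precision and sensitivity.
    """
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    counts = cm.counts
    N = cm.N
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = N - tp - fn - fp

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    pre_i = _safe(tp, tp + fp)
    sen_i = _safe(tp, tp + fn)
    spc_i = _safe(tn, tn + fp)
    if average == "macro":
        pre, sen, spc = pre_i.mean(), sen_i.mean(), spc_i.mean()
    else:
        pre = tp.sum() / max(tp.sum() + fp.sum(), 1.0)
        sen = tp.sum() / max(tp.sum() + fn.sum(), 1.0)
        spc = tn.sum() / max(tn.sum() + fp.sum(), 1.0)
    f = 0.0 if pre + sen == 0 else 2 * pre * sen / (pre + sen)
    return MetricsReport(
        accuracy=multiclass_accuracy(cm),
        precision=float(pre), sensitivity=float(sen), specificity=float(spc),
        f_score=float(f), confusion=cm,
        per_class={"precision": pre_i, "sensitivity": sen_i,
                   "specificity": spc_i},
        average=average)


@dataclass
class CurveSet:
    """An ordered (x, y) point list with its trapezoidal AUC."""

    kind: str  # "ROC" or "PR"
    points: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        x = self.points[:, 0]
        if (np.diff(x) < -1e-12).any():
            raise ValueError("curve x must be non-decreasing")
        if self.kind == "ROC":
            if not (np.allclose(self.points[0], (0, 0))
                    and np.allclose(self.points[-1], (1, 1))):
                raise ValueError("ROC must run from (0,0) to (1,1)")


def _collapse_steps(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper envelope of a step curve: unique x, max y per x."""
    ux = np.unique(x)
    uy = np.array([y[x == v].max() for v in ux])
    return ux, uy


def multiclass_curves(scores: np.ndarray, y_true: Sequence[int],
                      kind: str = "ROC") -> CurveSet:
    """Macro-averaged one-vs-rest ROC or PR curve.

    Per-class curves are computed over score thresholds, interpolated onto
    the shared grid of all observed x values, and averaged; the AUC is the
    trapezoidal area of the averaged curve. Classes absent from ``y_true``
    are skipped with a warning. For voting ensembles the score for class i
    is the vote fraction F_i / member count.
    """
    if kind not in ("ROC", "PR"):
        raise ValueError("kind must be 'ROC' or 'PR'")
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true, dtype=int)
    C = scores.shape[1]
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for c in range(C):
        pos = y_true == c
        if not pos.any() or pos.all():
            warnings.warn(f"class {c} absent from one side of y_true; skipped")
            continue
        if kind == "ROC":
            fpr, tpr, _ = _sk_roc(pos.astype(int), scores[:, c])
            curves.append(_collapse_steps(fpr, tpr))
        else:
            prec, rec, _ = _sk_pr(pos.astype(int), scores[:, c])
            curves.append(_collapse_steps(rec[::-1], prec[::-1]))
    if not curves:
        raise ValueError("no class with both positives and negatives")
    grid = np.unique(np.concatenate(
        [x for x, _ in curves] + [np.array([0.0, 1.0])]))
    mean_y = np.mean([np.interp(grid, x, y) for x, y in curves], axis=0)
    points = np.column_stack([grid, mean_y])
    if kind == "ROC" and mean_y[0] > 0:
        points = np.vstack([[0.0, 0.0], points])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return CurveSet(kind, points, auc)


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float],
                      ) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney) test with midrank ties.

    Exact null enumeration when both samples have at most 10 values and
    there are no ties; normal approximation with tie correction otherwise.
    Fully tied inputs (zero rank variance) give p = 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) \
        else "asymptotic"
    res = _scipy_stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class RunSetSummary:
    """Boxplot statistics of final fitnesses plus the mean convergence trace."""

    final_scores: np.ndarray
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    mean_trace: np.ndarray

    def to_dict(self) -> dict:
        return {
            "final_scores": [float(x) for x in self.final_scores],
            "median": self.median, "q1": self.q1, "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": [float(x) for x in self.outliers],
            "mean_trace": [float(x) for x in self.mean_trace],
        }


def run_set_summary(results: Sequence[SearchResult]) -> RunSetSummary:
    """Stability/convergence summary of repeated runs of one optimizer."""
    if not results:
        raise ValueError("need at least one result")
    lengths = {len(r.trace) for r in results}
    if len(lengths) != 1:
        raise ValueError("ragged traces; all runs must share a trace length")
    finals = np.array([r.best.fitness for r in results], dtype=float)
    q1, med, q3 = np.percentile(finals, [25, 50, 75])
    iqr = q3 - q1
    inside = finals[(finals >= q1 - 1.5 * iqr) & (finals <= q3 + 1.5 * iqr)]
    outliers = finals[(finals < q1 - 1.5 * iqr) | (finals > q3 + 1.5 * iqr)]
    traces = np.array([r.trace for r in results], dtype=float)
    return RunSetSummary(finals, float(med), float(q1), float(q3),
                         float(inside.min()), float(inside.max()),
                         outliers, traces.mean(axis=0))


# ---------------------------------------------------------------------------
# Nested cross-validated pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Full run settings for the cross-validated select-and-vote pipeline.

    ``leak_compat`` reproduces the preprocess-once / select-once-on-all-data
    protocol (statistically leak-prone but matching how results computed
    before splitting would be obtained); the default fits imputation and
    normalization statistics and runs selection inside each training fold.
    """

    trader: TraderConfig = field(default_factory=TraderConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    ensemble_size: int = 5
    outer_folds: int = 5
    selector: str = "trader"  # or "random" (budget-matched baseline)
    tie_policy: str = "fitness_weighted"
    leak_compat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.outer_folds < 2:
            raise ValueError("outer_folds must be >= 2")
        if self.selector not in ("trader", "random"):
            raise ValueError("selector must be 'trader' or 'random'")


@dataclass
class FoldDetail:
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    member_subsets: list[list[int]]
    member_fitnesses: list[float]


@dataclass
class CVRunResult:
    metrics: MetricsReport
    roc: CurveSet
    pr: CurveSet
    folds: list[FoldDetail]
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray


def _run_selector(table: DataTable, config: PipelineConfig, seed: int,
                  ) -> SearchResult:
    tcfg = TraderConfig(**{**config.trader.__dict__, "seed": seed})
    objective = SubsetObjective(
        table, ObjectiveConfig(**{**config.objective.__dict__, "seed": seed}))
    if config.selector == "trader":
        return trader_search(table, objective, tcfg)
    budget = tcfg.pop_size + tcfg.iterations * math.ceil(
        tcfg.change_fraction * tcfg.pop_size)
    return random_search_baseline(table, objective, budget,
                                  tcfg.subset_size, seed)


def cross_validated_run(table: DataTable, config: PipelineConfig,
                        ) -> CVRunResult:
    """Outer stratified k-fold evaluation of the select-and-vote pipeline.

    Per fold, imputation and normalization statistics are fit on the
    training part, the selector produces ``ensemble_size`` subsets on the
    training part, a voting ensemble is trained on it, and the held-out
    part is predicted. Predictions are pooled over folds into one confusion
    matrix and one score matrix. Fully determined by the run seed.
    """
    folds = stratified_folds(table.labels,
                             config.outer_folds,
                             derive_seed(config.seed, 0))
    n = table.n_samples
    C = table.class_count
    y_pred = np.full(n, -1, dtype=int)
    scores = np.zeros((n, C))
    details: list[FoldDetail] = []

    if config.leak_compat:
        from .preprocess import preprocess as _pre
        full, _, _ = _pre(table)
        shared_results = [
            _run_selector(full, config, derive_seed(config.seed, 1, r))
            for r in range(config.ensemble_size)
        ]

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if config.leak_compat:
            tr = full.restrict_rows(train_idx)
            te = full.restrict_rows(test_idx)
            results = shared_results
        else:
            tr = table.restrict_rows(train_idx)
            te = table.restrict_rows(test_idx)
            tr, _ = impute_missing(tr)
            te, _ = impute_missing(te, reference=tr)
            tr, stats = min_max_normalize(tr)
            te = apply_min_max(te, stats)
            results = [
                _run_selector(tr, config, derive_seed(config.seed, 1, f, r))
                for r in range(config.ensemble_size)
            ]
        ensemble = build_ensemble(tr, results, config.objective,
                                  config.tie_policy)
        y_pred[test_idx] = vote_predict(ensemble, te.values)
        scores[test_idx] = vote_scores(ensemble, te.values)
        details.append(FoldDetail(
            f, train_idx, np.asarray(test_idx),
            [[int(c) for c in r.best.cols] for r in results],
            [float(r.best.fitness) for r in results]))

    cm = confusion(table.labels, y_pred, C)
    return CVRunResult(
        metrics=metrics_report(cm),
        roc=multiclass_curves(scores, table.labels, "ROC"),
        pr=multiclass_curves(scores, table.labels, "PR"),
        folds=details, y_true=table.labels.copy(), y_pred=y_pred,
        scores=scores)
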