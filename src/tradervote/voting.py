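"""Majority-voting ensemble over independently selected feature subsets.

Each member pairs a feature subset (typically the best subset of one
optimizer run) with a classifier trained on those columns. For a sample,
the per-class vote count F_i is the number of members predicting class i;
the ensemble's prediction is argmax_i F_i. Ties are broken by summing the
member fitnesses behind each tied class (``fitness_weighted``), with the
lowest class index as the final fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatable import DataTable
from .objective import ObjectiveConfig, _make_svm
from .trader import CandidateSolution, SearchResult


@dataclass
class EnsembleMember:
    subset: CandidateSolution
    model: object  # anything with .predict on the subset's columns
    source_tag: str = ""
    member_fitness: float = 0.0


@dataclass
class EnsembleModel:
    members: list[EnsembleMember]
    class_count: int
    n_features: int
    tie_policy: str = "fitness_weighted"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.tie_policy not in ("fitness_weighted", "lowest_index"):
            raise ValueError("unknown tie policy")
        for m in self.members:
            classes = getattr(m.model, "classes_", None)
            if classes is not None and len(classes) != self.class_count:
                raise ValueError("members disagree on the class count")

    def to_manifest(self) -> dict:
        return {
            "class_count": self.class_count,
            "tie_policy": self.tie_policy,
            "members": [
                {
                    "source_tag": m.source_tag,
                    "selected_features": [int(c) for c in m.subset.cols],
                    "fitness": float(m.member_fitness),
                }
                for m in self.members
            ],
        }


def build_ensemble(table: DataTable, search_results: Sequence[SearchResult],
                   objective_config: ObjectiveConfig | None = None,
                   tie_policy: str = "fitness_weighted") -> EnsembleModel:
    """Train one SVM per search result on its best subset's columns."""
    if not search_results:
        raise ValueError("need at least one search result")
    cfg = objective_config or ObjectiveConfig()
    members = []
    for r, res in enumerate(search_results):
        cols = res.best.cols
        model = _make_svm(cfg).fit(table.values[:, cols], table.labels)
        members.append(EnsembleMember(
            subset=res.best.copy(), model=model,
            source_tag=f"{res.method}-seed{res.seed}",
            member_fitness=float(res.best.fitness)))
    return EnsembleModel(members, table.class_count, table.n_features,
                         tie_policy)


def _as_matrix(ensemble: EnsembleModel, sample: np.ndarray) -> np.ndarray:
    X = np.asarray(sample, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != ensemble.n_features:
        raise ValueError(
            f"sample has {X.shape[1]} features, ensemble expects "
            f"{ensemble.n_features}")
    return X


def member_predictions(ensemble: EnsembleModel, sample: np.ndarray) -> np.ndarray:
    """(n_members, n_samples) matrix of per-member class predictions."""
    X = _as_matrix(ensemble, sample)
    return np.stack([
        np.asarray(m.model.predict(X[:, m.subset.cols]), dtype=int)
        for m in ensemble.members
    ])


def vote_counts(ensemble: EnsembleModel, sample: np.ndarray) -> np.ndarray:
    """Per-class vote counts F_i; rows sum to the member count.

    Returns shape (C,) for a single sample, (n, C) for a matrix.
    """
    single = np.asarray(sample).ndim == 1
    preds = member_predictions(ensemble, sample)
    C = ensemble.class_count
    counts = np.stack([np.bincount(preds[:, s], minlength=C)
                       for s in range(preds.shape[1])])
    return counts[0] if single else counts


def vote_predict(ensemble: EnsembleModel, sample: np.ndarray):
    """Majority class argmax_i F_i with the configured tie policy."""
    single = np.asarray(sample).ndim == 1
    preds = member_predictions(ensemble, sample)
    C = ensemble.class_count
    fitness = np.array([m.member_fitness for m in ensemble.members])
    out = np.empty(preds.shape[1], dtype=int)
    for s in range(preds.shape[1]):
        counts = np.bincount(preds[:, s], minlength=C)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1 or ensemble.tie_policy == "lowest_index":
            out[s] = tied[0]
        else:
            weights = np.array([
                fitness[preds[:, s] == c].sum() for c in tied])
            out[s] = tied[np.flatnonzero(weights == weights.max())[0]]
    return int(out[0]) if single else out


def vote_scores(ensemble: EnsembleModel, sample: np.ndarray) -> np.ndarray:
    """Per-class scores F_i / member count, usable for ROC/PR curves."""
    counts = vote_counts(ensemble, sample)
    return counts / len(ensemble.members)
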