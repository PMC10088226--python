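"""Two-phase preprocessing: correlated-neighbor imputation, then min-max scaling.

Missing cells of a sample are completed from up to ten other samples that
(i) are complete where the sample is missing and (ii) share a Pearson
correlation above 0.5 with it over the jointly observed features. The
imputed value is the correlation-weighted mean of the neighbours' values in
that column; when no neighbour qualifies, the column mean over observed
values is used and the cell is recorded as a fallback. Normalization maps
every column to [0, 1] via (x - min_j) / (max_j - min_j); the per-column
statistics are returned so that held-out folds can be transformed with
training-fold statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatable import DataTable

#: minimum number of jointly observed positions for a defined correlation
MIN_SHARED = 3


def pearson_correlation(x: np.ndarray, y: np.ndarray,
                        shared_mask: Optional[np.ndarray] = None) -> float:
    """Pearson r over jointly observed positions; NaN when undefined.

    Undefined means fewer than three shared positions, or zero variance in
    either vector over the shared positions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if shared_mask is None:
        shared_mask = ~np.isnan(x) & ~np.isnan(y)
    shared_mask = np.asarray(shared_mask, dtype=bool)
    xs, ys = x[shared_mask], y[shared_mask]
    if xs.size < MIN_SHARED:
        return float("nan")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    return float(np.corrcoef(xs, ys)[0, 1])


@dataclass
class ImputationReport:
    """Record of what :func:`impute_missing` filled and how."""

    #: (sample index, feature index, imputed value, neighbour count used)
    filled_cells: list[tuple[int, int, float, int]] = field(default_factory=list)
    #: cells filled by the column-mean fallback (subset of filled_cells)
    fallback_cells: list[tuple[int, int]] = field(default_factory=list)
    #: samples whose neighbours came from the per-needed-column relaxation
    second_chance_rows: list[int] = field(default_factory=list)


def impute_missing(table: DataTable, max_neighbors: int = 10,
                   min_corr: float = 0.5,
                   reference: Optional[DataTable] = None,
                   ) -> tuple[DataTable, ImputationReport]:
    """Complete every missing cell of ``table``.

    Neighbours are drawn from ``reference`` when given (e.g. the training
    fold when transforming held-out data), otherwise from the other rows of
    ``table`` itself. The strict neighbour rule requires a fully complete
    sample; when it yields no qualifying neighbour, a second-chance pass
    accepts samples complete only in the needed columns, recorded in the
    report.
    """
    out = table.copy()
    report = ImputationReport()
    vals, mask = out.values, out.missing_mask
    if reference is None:
        pool_vals, pool_mask = vals, mask
        self_pool = True
    else:
        pool_vals, pool_mask = reference.values, reference.missing_mask
        self_pool = False

    pool_complete = ~pool_mask.any(axis=1)
    rows = np.flatnonzero(mask.any(axis=1))
    for i in rows:
        if mask[i].all():
            raise ValueError(f"sample {i} is entirely missing")
        miss_cols = np.flatnonzero(mask[i])
        obs_i = ~mask[i]

        neighbors = _find_neighbors(
            i if self_pool else -1, vals[i], obs_i, miss_cols,
            pool_vals, pool_mask, pool_complete, min_corr, max_neighbors)
        if neighbors is None:
            neighbors = _find_neighbors(
                i if self_pool else -1, vals[i], obs_i, miss_cols,
                pool_vals, pool_mask, pool_complete, min_corr, max_neighbors,
                strict=False)
            if neighbors is not None:
                report.second_chance_rows.append(int(i))

        for j in miss_cols:
            if neighbors is not None:
                ids, rs = neighbors
                w = rs / rs.sum()
                v = float(np.dot(w, pool_vals[ids, j]))
                report.filled_cells.append((int(i), int(j), v, len(ids)))
            else:
                col_obs = pool_vals[~pool_mask[:, j], j]
                if col_obs.size == 0:
                    raise ValueError(
                        f"column {j} has no observed values; cannot fall back")
                v = float(col_obs.mean())
                report.filled_cells.append((int(i), int(j), v, 0))
                report.fallback_cells.append((int(i), int(j)))
            vals[i, j] = v
    mask[:] = False
    out.validate()
    return out, report


def _find_neighbors(self_id, x, obs_x, miss_cols, pool_vals, pool_mask,
                    pool_complete, min_corr, max_neighbors, strict=True):
    """Qualifying (ids, correlations), or None when no neighbour qualifies."""
    if strict:
        cand = np.flatnonzero(pool_complete)
    else:
        ok = ~pool_mask[:, miss_cols].any(axis=1)
        cand = np.flatnonzero(ok)
    rs, ids = [], []
    for t in cand:
        if t == self_id:
            continue
        shared = obs_x & ~pool_mask[t]
        r = pearson_correlation(x, pool_vals[t], shared)
        if np.isnan(r) or r <= min_corr:
            continue
        rs.append(r)
        ids.append(t)
    if not ids:
        return None
    order = np.argsort(rs)[::-1][:max_neighbors]
    return np.asarray(ids)[order], np.asarray(rs)[order]


@dataclass
class NormStats:
    """Per-column (min, max) fitted on a training table."""

    min_: np.ndarray
    max_: np.ndarray


def min_max_normalize(table: DataTable) -> tuple[DataTable, NormStats]:
    """Scale every column to [0, 1]; constant columns map to 0.

    Requires a complete table (run :func:`impute_missing` first). Returns
    the fitted statistics for transforming held-out folds.
    """
    if table.missing_mask.any():
        raise ValueError("normalization requires a table with no missing cells")
    stats = NormStats(table.values.min(axis=0), table.values.max(axis=0))
    return apply_min_max(table, stats), stats


def apply_min_max(table: DataTable, stats: NormStats) -> DataTable:
    """Apply previously fitted min/max statistics (training-fold transform)."""
    if table.missing_mask.any():
        raise ValueError("normalization requires a table with no missing cells")
    out = table.copy()
    span = stats.max_ - stats.min_
    safe = np.where(span == 0, 1.0, span)
    out.values = (out.values - stats.min_) / safe
    out.values[:, span == 0] = 0.0
    out.feature_kinds = [
        "binary" if _obs_binary(out.values[:, j]) else "numeric"
        for j in range(out.n_features)
    ]
    return out


def _obs_binary(col: np.ndarray) -> bool:
    return bool(np.all(np.isin(col, (0.0, 1.0))))


def preprocess(table: DataTable, max_neighbors: int = 10, min_corr: float = 0.5,
               ) -> tuple[DataTable, ImputationReport, NormStats]:
    """Impute then normalize; the composite used by the CLI and evaluation."""
    imputed, report = impute_missing(table, max_neighbors, min_corr)
    normed, stats = min_max_normalize(imputed)
    return normed, report, stats
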