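"""Tabular dataset container and UCI-style CSV input/output.

The unit of data throughout the package is the :class:`DataTable`: a
samples x features matrix of real numbers with an integer class-label
vector, a boolean missing-cell mask, and per-feature metadata. Rows are
samples and columns are features. All indices exposed in files are 0-based
column positions; the search operators use 1-based indices internally (see
:mod:`tradervote.trader`) with conversion at the boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_MISSING_TOKENS = frozenset({"", "?", "NA"})


@dataclass
class DataTable:
    """Samples x features matrix with labels and a missing-cell mask.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float matrix. Missing cells hold NaN.
    labels
        Length ``n_samples`` integer vector with values in ``{0..C-1}``.
    feature_names
        Length ``n_features`` list of column names.
    missing_mask
        Boolean matrix, same shape as ``values``; True marks a missing cell.
    label_names
        Original label strings, index ``c`` -> name of class ``c``.
    feature_kinds
        Per-feature tag, ``"binary"`` iff the observed values of the column
        are a subset of ``{0, 1}``, else ``"numeric"``. Informational only.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    missing_mask: np.ndarray
    label_names: list[str]
    feature_kinds: list[str] = field(default_factory=list)
    strict: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not self.feature_kinds:
            self.feature_kinds = [
                "binary" if _is_binary(self.values[:, j], self.missing_mask[:, j])
                else "numeric"
                for j in range(self.values.shape[1])
            ]
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        v, y, m = self.values, self.labels, self.missing_mask
        if v.ndim != 2:
            raise ValueError("values must be a 2-d matrix")
        n, d = v.shape
        if d < 1:
            raise ValueError("need at least one feature column")
        if n < 2:
            raise ValueError("need at least two samples")
        if y.shape != (n,):
            raise ValueError("labels length must match the number of rows")
        if m.shape != v.shape:
            raise ValueError("missing_mask shape must match values")
        C = len(self.label_names)
        if C < 2:
            raise ValueError("fewer than 2 classes")
        if y.min() < 0 or y.max() >= C:
            raise ValueError("labels must lie in {0..C-1}")
        if self.strict and len(np.unique(y)) != C:
            raise ValueError("every class must have at least one sample")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match columns")
        nan_cells = np.isnan(v)
        if not np.array_equal(nan_cells, m):
            raise ValueError("missing_mask must flag exactly the NaN cells")

    # -- properties -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def class_count(self) -> int:
        return len(self.label_names)

    # -- derived tables -------------------------------------------------
    def copy(self) -> "DataTable":
        return DataTable(
            self.values.copy(),
            self.labels.copy(),
            list(self.feature_names),
            self.missing_mask.copy(),
            list(self.label_names),
            list(self.feature_kinds),
            strict=self.strict,
        )

    def restrict_rows(self, idx: Sequence[int], strict: bool = False) -> "DataTable":
        """Row-subset table (e.g. a CV fold); class presence is not enforced."""
        idx = np.asarray(idx, dtype=int)
        return DataTable(
            self.values[idx],
            self.labels[idx],
            list(self.feature_names),
            self.missing_mask[idx],
            list(self.label_names),
            list(self.feature_kinds),
            strict=strict,
        )

    # -- I/O ------------------------------------------------------------
    def to_csv(self, path: str | Path, label_column: str = "label",
               missing_token: str = "?") -> Path:
        """Write an RFC-4180 CSV with a header row; missing cells as ``?``."""
        path = Path(path)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(list(self.feature_names) + [label_column])
            for i in range(self.n_samples):
                row: list[str] = []
                for j in range(self.n_features):
                    if self.missing_mask[i, j]:
                        row.append(missing_token)
                    else:
                        row.append(repr(float(self.values[i, j])))
                row.append(self.label_names[self.labels[i]])
                w.writerow(row)
        return path


def _is_binary(col: np.ndarray, miss: np.ndarray) -> bool:
    obs = col[~miss]
    return obs.size > 0 and bool(np.all(np.isin(obs, (0.0, 1.0))))


def read_csv_dataset(path: str | Path, label_column: str | int,
                     missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
                     ) -> DataTable:
    """Read a UCI-style CSV into a :class:`DataTable`.

    Cells matching a missing token (default ``""``, ``"?"``, ``"NA"``) are
    flagged in the missing mask. Class labels are mapped to ``{0..C-1}`` by
    first-appearance order; the mapping is retained in ``label_names``.
    """
    tokens = set(missing_tokens)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if isinstance(label_column, int):
        if label_column < 0 or label_column >= df.shape[1]:
            raise ValueError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        label_name = label_column
    feat_cols = [c for c in df.columns if c != label_name]
    if not feat_cols:
        raise ValueError("need at least one non-label column")

    raw_labels = df[label_name].tolist()
    label_names: list[str] = []
    seen: dict[str, int] = {}
    labels = np.empty(len(raw_labels), dtype=int)
    for i, s in enumerate(raw_labels):
        if s in tokens:
            raise ValueError(f"missing label in row {i}")
        if s not in seen:
            seen[s] = len(label_names)
            label_names.append(s)
        labels[i] = seen[s]
    if len(label_names) < 2:
        raise ValueError("fewer than 2 classes in the label column")

    n, d = len(df), len(feat_cols)
    values = np.empty((n, d), dtype=float)
    mask = np.zeros((n, d), dtype=bool)
    for j, c in enumerate(feat_cols):
        col = df[c].tolist()
        for i, s in enumerate(col):
            if s in tokens:
                values[i, j] = np.nan
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(s)
                except ValueError as exc:
                    raise ValueError(
                        f"non-numeric cell {s!r} in column {c!r}, row {i}"
                    ) from exc
        if mask[:, j].all():
            raise ValueError(f"column {c!r} is entirely missing")
    return DataTable(values, labels, feat_cols, mask, label_names)


# ---------------------------------------------------------------------------
# Run-artifact serialization
# ---------------------------------------------------------------------------

def write_result_bundle(result: Any, path: str | Path) -> list[Path]:
    """Serialize a run artifact to structured text files under ``path``.

    SearchResult, RunSetSummary, MetricsReport and dictionaries go to JSON;
    CurveSet curve points and DataFrame tables go to CSV (the curve's AUC to
    a JSON sidecar). Returns the manifest of created files.
    """
    from .evaluation import CurveSet, MetricsReport, RunSetSummary
    from .trader import SearchResult

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []

    def _json(name: str, obj: Any) -> None:
        p = path / name
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)
        created.append(p)

    if isinstance(result, SearchResult):
        _json("search_result.json", result.to_dict())
    elif isinstance(result, MetricsReport):
        _json("metrics.json", result.to_dict())
    elif isinstance(result, CurveSet):
        p = path / f"{result.kind.lower()}_curve.csv"
        pd.DataFrame(result.points, columns=["x", "y"]).to_csv(p, index=False)
        created.append(p)
        _json(f"{result.kind.lower()}_auc.json",
              {"kind": result.kind, "auc": result.auc})
    elif isinstance(result, RunSetSummary):
        _json("run_summary.json", result.to_dict())
        p = path / "mean_trace.csv"
        pd.DataFrame({"iteration": np.arange(len(result.mean_trace)),
                      "mean_best": result.mean_trace}).to_csv(p, index=False)
        created.append(p)
    elif isinstance(result, pd.DataFrame):
        p = path / "table.csv"
        result.to_csv(p, index=False)
        created.append(p)
    elif isinstance(result, dict):
        _json("result.json", result)
    else:
        raise TypeError(f"cannot serialize artifact of type {type(result)!r}")
    return created


def load_search_result(path: str | Path) -> "Any":
    from .trader import SearchResult

    with open(path) as fh:
        return SearchResult.from_dict(json.load(fh))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
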