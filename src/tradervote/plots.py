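"""Plot rendering for convergence, stability, ROC/PR curves and AUC bars."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import CurveSet, RunSetSummary  # noqa: E402


def plot_convergence(summaries: Mapping[str, RunSetSummary],
                     path: str | Path) -> Path:
    """Mean best-so-far fitness per iteration, one line per optimizer."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, s in summaries.items():
        ax.plot(range(len(s.mean_trace)), s.mean_trace, label=name)
    ax.set_xlabel("iteration")
    ax.set_ylabel("mean best accuracy")
    ax.legend()
    return _save(fig, path)


def plot_stability(summaries: Mapping[str, RunSetSummary],
                   path: str | Path) -> Path:
    """Boxplots of final fitnesses across repeated runs."""
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(summaries)
    ax.boxplot([summaries[n].final_scores for n in names], tick_labels=names)
    ax.set_ylabel("final accuracy")
    return _save(fig, path)


def plot_curves(curves: Mapping[str, CurveSet], path: str | Path) -> Path:
    """Overlay ROC (or PR) curves of several classifiers."""
    fig, ax = plt.subplots(figsize=(5, 5))
    kind = None
    for name, c in curves.items():
        kind = c.kind
        ax.plot(c.points[:, 0], c.points[:, 1],
                label=f"{name} (AUC={c.auc:.3f})")
    if kind == "ROC":
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
    else:
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
    ax.legend()
    return _save(fig, path)


def plot_auc_bars(aucs: Mapping[str, float], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    names = list(aucs)
    ax.bar(names, [aucs[n] for n in names])
    ax.set_ylabel("AUC")
    ax.set_ylim(0, 1.05)
    return _save(fig, path)


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
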