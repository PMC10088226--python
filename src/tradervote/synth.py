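"""Synthetic UCI-like classification tables with known ground truth.

The generator draws C class centroids in the informative subspace at
pairwise distances proportional to ``class_sep``, adds Gaussian noise of
standard deviation ``noise_sd`` to the informative columns, fills the
remaining columns with standard Gaussian noise (a fraction of them
thresholded to {0, 1} to mimic binary attributes), balances the class
labels up to the division remainder, and optionally plants missing cells
uniformly at random without ever emptying a row or a column. Everything is
fully determined by the seed, and the informative column index set is
returned as ground truth — which no real dataset provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datatable import DataTable


@dataclass
class SyntheticSpec:
    """Generator settings; the defaults give a 300 x 50 two-class table with
    5 informative columns at wide (near-separable) class separation."""

    n_samples: int = 300
    n_features: int = 50
    n_informative: int = 5
    class_count: int = 2
    class_sep: float = 6.0
    noise_sd: float = 1.0
    binary_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_informative < 1 or self.n_informative > self.n_features:
            raise ValueError("need 1 <= n_informative <= n_features")
        if self.class_count < 2:
            raise ValueError("need at least 2 classes")
        if self.n_informative <= 30 and self.class_count > 2**self.n_informative:
            raise ValueError(
                "class_count exceeds the number of distinct centroid "
                "patterns (2**n_informative)")
        if self.n_samples < 2 * self.class_count:
            raise ValueError("need at least 2 samples per class")
        if self.class_sep < 0 or self.noise_sd < 0:
            raise ValueError("class_sep and noise_sd must be non-negative")
        if not 0 <= self.binary_fraction <= 1:
            raise ValueError("binary_fraction must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


def _draw_centroids(C: int, p: int, class_sep: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Class centroids as random sign patterns, scaled so the minimum
    pairwise distance equals ``class_sep``.

    Every informative coordinate is forced to split the classes (no
    coordinate may take the same sign for all classes), so each
    ground-truth column genuinely separates at least one class pair —
    otherwise "informative" would be ill-defined for that column.
    """
    if p <= 30:
        codes = rng.choice(2**p, size=C, replace=False)
        bits = (codes[:, None] >> np.arange(p)) & 1
    else:  # collision probability ~ C^2 / 2^p is negligible
        bits = rng.integers(0, 2, size=(C, p))
    signs = bits.astype(float) * 2 - 1
    for j in range(p):
        # a constant column separates nothing; flipping one class's sign
        # cannot collide with another pattern (all others share that sign)
        if np.all(signs[:, j] == signs[0, j]):
            signs[int(rng.integers(C)), j] *= -1
    d_min = min(np.linalg.norm(signs[i] - signs[j])
                for i in range(C) for j in range(i + 1, C))
    return signs * (class_sep / d_min)


def generate(spec: SyntheticSpec) -> tuple[DataTable, list[int]]:
    """Generate a table and the ground-truth informative column indices."""
    rng = np.random.default_rng(spec.seed)
    n, d, p, C = (spec.n_samples, spec.n_features, spec.n_informative,
                  spec.class_count)

    centroids = _draw_centroids(C, p, spec.class_sep, rng)

    labels = np.arange(n) % C
    rng.shuffle(labels)

    informative = centroids[labels] + rng.normal(scale=spec.noise_sd,
                                                 size=(n, p))
    n_noise = d - p
    noise = rng.normal(size=(n, n_noise))
    n_bin = int(round(spec.binary_fraction * n_noise))
    if n_bin:
        bin_cols = rng.choice(n_noise, size=n_bin, replace=False)
        noise[:, bin_cols] = (noise[:, bin_cols] > 0).astype(float)

    order = rng.permutation(d)
    values = np.empty((n, d))
    values[:, order[:p]] = informative
    values[:, order[p:]] = noise
    ground_truth = sorted(int(c) for c in order[:p])

    mask = np.zeros((n, d), dtype=bool)
    if spec.missing_rate > 0:
        total = int(round(spec.missing_rate * n * d))
        cells = rng.choice(n * d, size=min(total, n * d), replace=False)
        row_obs = np.full(n, d)
        col_obs = np.full(d, n)
        for cell in cells:
            i, j = divmod(int(cell), d)
            if row_obs[i] > 1 and col_obs[j] > 1:
                mask[i, j] = True
                row_obs[i] -= 1
                col_obs[j] -= 1
        values[mask] = np.nan

    table = DataTable(
        values, labels,
        [f"f{j}" for j in range(d)], mask,
        [f"c{c}" for c in range(C)])
    return table, ground_truth


#: Table-of-datasets presets: (name, instances, features, classes,
#: informative subset size, has missing cells, mixed numeric/binary columns)
_PRESET_ROWS = [
    ("LIV", 345, 6, 2, 4, False, True),
    ("PID", 768, 8, 2, 4, False, False),
    ("SHD", 270, 13, 2, 5, False, True),
    ("CHD2", 303, 13, 2, 5, False, True),
    ("CHD5", 303, 13, 5, 5, False, True),
    ("HEP", 150, 19, 2, 6, True, True),
    ("PAR", 197, 22, 2, 6, True, False),
    ("WDBC", 569, 31, 2, 6, False, False),
    ("LUNG", 32, 56, 3, 8, True, True),
    ("ARRYTM", 452, 279, 16, 9, True, False),
    ("PARKINSON", 756, 754, 2, 10, False, True),
    ("ARCENE", 900, 10000, 2, 10, False, False),
    ("GENEEXPR", 801, 20531, 5, 15, False, False),
]

#: cell-wise missing rate used for presets of datasets that carry missing
#: values; a few percent matches how sparsely UCI clinical files are holed
PRESET_MISSING_RATE = 0.03
#: fraction of noise columns thresholded to {0,1} for mixed-type presets
PRESET_BINARY_FRACTION = 0.2


def table1_presets(seed: int = 0) -> list[SyntheticSpec]:
    """One synthetic spec per benchmark dataset shape (13 presets)."""
    specs = []
    for i, (name, n, d, c, k, miss, mixed) in enumerate(_PRESET_ROWS):
        specs.append(SyntheticSpec(
            n_samples=n, n_features=d, n_informative=k, class_count=c,
            binary_fraction=PRESET_BINARY_FRACTION if mixed else 0.0,
            missing_rate=PRESET_MISSING_RATE if miss else 0.0,
            seed=seed + i, name=name))
    return specs


def preset_by_name(name: str, seed: int = 0) -> SyntheticSpec:
    for spec in table1_presets(seed):
        if spec.name.lower() == name.lower():
            return spec
    raise KeyError(f"unknown preset {name!r}")
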