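"""The Trader population-based wrapper feature-selection algorithm.

A population of candidate solutions — each a fixed-length vector of k
distinct feature indices — is randomly partitioned into groups ("traders").
Within a group the best-fitness member is the master (MCS) and the rest are
slaves (SCS); a group's finance is the sum of its members' fitnesses. Each
iteration a fraction of the population is modified by one of three
stochastic operators:

* retailing      — a slave's selected variables are perturbed by
                   V_j <- V_j + sign * uniform_int(0, V_j), a minor local move;
* distributing   — a slave copies randomly chosen variables from its
                   group's master;
* import/export  — a master (importer) receives variables from a randomly
                   chosen other master (exporter), pairing randomly drawn
                   position sets of equal size.

Indices are 1-based inside the operators so the multiplicative retailing
perturbation can move a variable off any value; conversion to 0-based
happens at the I/O boundary. After each operator a repair step clamps
indices to [1..n_features] and replaces duplicates by uniform draws from
the unused indices, so every emitted solution stays a valid k-subset.

Acceptance is elitist — a modified candidate replaces its originator only
when its fitness is not worse — which makes the best-so-far trace
non-decreasing. The number of objective calls is exactly
``pop_size + iterations * ceil(change_fraction * pop_size)``, enabling
budget-parity comparisons with other optimizers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .datatable import DataTable
from .objective import ObjectiveConfig, SubsetObjective

logger = logging.getLogger(__name__)


@dataclass
class CandidateSolution:
    """A k-subset of features: distinct 1-based indices plus a fitness."""

    indices: np.ndarray
    fitness: Optional[float] = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)

    @property
    def k(self) -> int:
        return self.indices.size

    @property
    def cols(self) -> np.ndarray:
        """Sorted 0-based column positions (the I/O convention)."""
        return np.sort(self.indices) - 1

    def validate(self, n_features: int) -> None:
        idx = self.indices
        if idx.size < 1 or idx.size > n_features:
            raise ValueError("subset size must be in [1, n_features]")
        if idx.min() < 1 or idx.max() > n_features:
            raise ValueError("indices must lie in [1, n_features]")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("indices must be distinct")

    def copy(self) -> "CandidateSolution":
        return CandidateSolution(self.indices.copy(), self.fitness)


@dataclass
class TraderGroup:
    """A trader: member positions, its master, and the group finance."""

    member_ids: list[int]
    master_id: int = -1
    finance: float = 0.0

    def refresh(self, population: Sequence[CandidateSolution]) -> None:
        """Re-derive the master (max fitness, ties -> lowest id) and finance."""
        best_id, best_fit = -1, -np.inf
        total = 0.0
        for mid in self.member_ids:
            f = population[mid].fitness
            if f is None:
                raise ValueError("all member fitnesses must be set")
            total += f
            if f > best_fit:
                best_id, best_fit = mid, f
        self.master_id = best_id
        self.finance = total


@dataclass
class TraderConfig:
    """Search settings; the defaults are the reference experimental protocol
    (population 100, 50 iterations, 30% of candidate solutions changed per
    iteration, 5 groups)."""

    pop_size: int = 100
    iterations: int = 50
    change_fraction: float = 0.3
    n_groups: int = 5
    subset_size: int = 5
    seed: int = 0
    operator_mix: float = 0.5  # probability of retailing (vs distributing)

    def __post_init__(self) -> None:
        if self.pop_size < 1 or self.iterations < 0:
            raise ValueError("pop_size >= 1 and iterations >= 0 required")
        if not 0 < self.change_fraction <= 1:
            raise ValueError("change_fraction must be in (0, 1]")
        if self.n_groups < 1 or self.n_groups > self.pop_size:
            raise ValueError("need 1 <= n_groups <= pop_size")
        if not 0 <= self.operator_mix <= 1:
            raise ValueError("operator_mix must be a probability")


@dataclass
class SearchResult:
    """Outcome of one optimizer run."""

    best: CandidateSolution
    trace: list[float]
    objective_calls: int
    seed: int
    method: str = "trader"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "selected_features": [int(c) for c in self.best.cols],
            "fitness": float(self.best.fitness),
            "trace": [float(t) for t in self.trace],
            "objective_calls": int(self.objective_calls),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchResult":
        best = CandidateSolution(
            np.asarray(d["selected_features"], dtype=int) + 1, d["fitness"])
        return cls(best, list(d["trace"]), int(d["objective_calls"]),
                   int(d["seed"]), d.get("method", "trader"))


# ---------------------------------------------------------------------------
# Population and operators
# ---------------------------------------------------------------------------

def init_population(config: TraderConfig, n_features: int,
                    rng: np.random.Generator) -> list[CandidateSolution]:
    """Uniform random k-subsets of [1..n_features], fitness unset."""
    k = config.subset_size
    if k > n_features:
        raise ValueError("subset_size exceeds the number of features")
    return [
        CandidateSolution(rng.choice(n_features, size=k, replace=False) + 1)
        for _ in range(config.pop_size)
    ]


def partition_groups(population: Sequence[CandidateSolution], n_groups: int,
                     rng: np.random.Generator) -> list[TraderGroup]:
    """Random partition into groups of near-equal size (difference <= 1)."""
    n = len(population)
    if n_groups > n:
        raise ValueError("more groups than population members")
    perm = rng.permutation(n)
    base, rem = divmod(n, n_groups)
    groups: list[TraderGroup] = []
    start = 0
    for g in range(n_groups):
        size = base + (1 if g < rem else 0)
        grp = TraderGroup([int(i) for i in perm[start:start + size]])
        grp.refresh(population)
        groups.append(grp)
        start += size
    return groups


def _repair(raw: np.ndarray, n_features: int,
            rng: np.random.Generator) -> np.ndarray:
    """Clamp to [1..n_features], then replace duplicates by unused indices."""
    fixed = np.clip(raw, 1, n_features)
    seen: set[int] = set()
    dup_pos: list[int] = []
    for pos, v in enumerate(fixed):
        if int(v) in seen:
            dup_pos.append(pos)
        else:
            seen.add(int(v))
    if dup_pos:
        unused = np.array(sorted(set(range(1, n_features + 1)) - seen))
        draws = rng.choice(unused.size, size=len(dup_pos), replace=False)
        for pos, d in zip(dup_pos, draws):
            fixed[pos] = unused[d]
    return fixed


def _select_positions(k: int, rng: np.random.Generator) -> np.ndarray:
    """Each position independently with probability 1/k; at least one forced."""
    mask = rng.random(k) < 1.0 / k
    if not mask.any():
        mask[rng.integers(k)] = True
    return np.flatnonzero(mask)


def retailing(scs: CandidateSolution, n_features: int,
              rng: np.random.Generator) -> CandidateSolution:
    """Minor local perturbation of a slave: V_j <- V_j + sign * U{0..V_j}."""
    new = scs.indices.copy()
    for j in _select_positions(scs.k, rng):
        sign = 1 if rng.integers(2) == 1 else -1
        delta = int(rng.integers(0, new[j] + 1))
        new[j] = new[j] + sign * delta
    return CandidateSolution(_repair(new, n_features, rng))


def distributing(scs: CandidateSolution, mcs: CandidateSolution,
                 rng: np.random.Generator, n_features: int | None = None,
                 ) -> CandidateSolution:
    """Copy randomly chosen variables of the group master into a slave."""
    if scs.k != mcs.k:
        raise ValueError("slave and master must have the same subset size")
    nf = n_features if n_features is not None else int(
        max(scs.indices.max(), mcs.indices.max()))
    new = scs.indices.copy()
    S = _select_positions(scs.k, rng)
    new[S] = mcs.indices[S]
    return CandidateSolution(_repair(new, nf, rng))


def import_export(importer_mcs: CandidateSolution,
                  exporter_mcs_list: Sequence[CandidateSolution],
                  rng: np.random.Generator, n_features: int | None = None,
                  ) -> CandidateSolution:
    """Transfer variables from a randomly chosen exporter master.

    Equal-size random position sets S (importer) and M (exporter) are drawn
    and paired in drawn order; |S| is capped at the exporter's subset size.
    """
    if not exporter_mcs_list:
        raise ValueError("need at least one exporter")
    exporter = exporter_mcs_list[int(rng.integers(len(exporter_mcs_list)))]
    nf = n_features if n_features is not None else int(
        max(importer_mcs.indices.max(), exporter.indices.max()))
    S = _select_positions(importer_mcs.k, rng)
    if S.size > exporter.k:
        S = rng.choice(S, size=exporter.k, replace=False)
    M = rng.choice(exporter.k, size=S.size, replace=False)
    new = importer_mcs.indices.copy()
    new[S] = exporter.indices[M]
    return CandidateSolution(_repair(new, nf, rng))


# ---------------------------------------------------------------------------
# Search loops
# ---------------------------------------------------------------------------

def trader_search(table: DataTable,
                  objective: Callable[[CandidateSolution], float] | None,
                  config: TraderConfig) -> SearchResult:
    """Run the Trader search; returns the best subset, trace, and call count.

    ``objective`` maps a candidate to a fitness in [0, 1]; when None, an
    SVM-accuracy :class:`~tradervote.objective.SubsetObjective` is built
    from the table. Exactly ``pop_size + iterations * m`` objective calls
    are made, with ``m = ceil(change_fraction * pop_size)``.
    """
    if objective is None:
        objective = SubsetObjective(table, ObjectiveConfig(seed=config.seed))
    n_features = table.n_features
    if config.subset_size > n_features:
        raise ValueError("subset_size exceeds the number of features")
    rng = np.random.default_rng(config.seed)

    population = init_population(config, n_features, rng)
    for cs in population:
        cs.fitness = _checked(objective, cs, iteration=0)
    best = max(population, key=lambda c: c.fitness).copy()
    trace = [best.fitness]

    groups = partition_groups(population, config.n_groups, rng)
    group_of: dict[int, TraderGroup] = {}
    for g in groups:
        for mid in g.member_ids:
            group_of[mid] = g

    m = math.ceil(config.change_fraction * config.pop_size)
    for it in range(1, config.iterations + 1):
        selected = rng.choice(config.pop_size, size=m, replace=False)
        proposals: list[tuple[int, CandidateSolution]] = []
        for idx in selected:
            idx = int(idx)
            grp = group_of[idx]
            if idx == grp.master_id:
                others = [population[g.master_id] for g in groups
                          if g is not grp]
                if others:
                    cand = import_export(population[idx], others, rng,
                                         n_features)
                else:  # single group: no trading partner, perturb locally
                    cand = retailing(population[idx], n_features, rng)
            elif rng.random() < config.operator_mix:
                cand = retailing(population[idx], n_features, rng)
            else:
                cand = distributing(population[idx],
                                    population[grp.master_id], rng, n_features)
            proposals.append((idx, cand))
        for idx, cand in proposals:
            cand.fitness = _checked(objective, cand, iteration=it)
            if cand.fitness >= population[idx].fitness:
                population[idx] = cand
        for g in groups:
            g.refresh(population)
        it_best = max(population, key=lambda c: c.fitness)
        if it_best.fitness > best.fitness:
            best = it_best.copy()
        trace.append(best.fitness)
        logger.info("iteration %d: best=%.4f calls=%d", it, best.fitness,
                    config.pop_size + it * m)

    return SearchResult(best, trace,
                        config.pop_size + config.iterations * m, config.seed)


def _checked(objective, cand, iteration: int) -> float:
    try:
        return float(objective(cand))
    except Exception as exc:
        raise RuntimeError(
            f"objective failed at iteration {iteration} on subset "
            f"{sorted(int(v) for v in cand.indices)}") from exc


def random_search_baseline(table: DataTable,
                           objective: Callable[[CandidateSolution], float] | None,
                           budget: int, k: int, seed: int,
                           block_size: int = 1) -> SearchResult:
    """Budget-matched uniform random search over k-subsets.

    Evaluates ``budget`` uniform random subsets and records the best-so-far
    after every ``block_size`` evaluations, giving a trace comparable with
    Trader runs at an identical objective-call count.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if k > table.n_features:
        raise ValueError("subset size exceeds the number of features")
    if objective is None:
        objective = SubsetObjective(table, ObjectiveConfig(seed=seed))
    rng = np.random.default_rng(seed)
    best: CandidateSolution | None = None
    trace: list[float] = []
    since_block = 0
    for _ in range(budget):
        cand = CandidateSolution(
            rng.choice(table.n_features, size=k, replace=False) + 1)
        cand.fitness = _checked(objective, cand, iteration=0)
        if best is None or cand.fitness > best.fitness:
            best = cand.copy()
        since_block += 1
        if since_block == block_size:
            trace.append(best.fitness)
            since_block = 0
    if since_block:
        trace.append(best.fitness)
    return SearchResult(best, trace, budget, seed, method="random")
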