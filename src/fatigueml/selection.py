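"""Feature-selection regimes.

Five regimes over the 25 eye/face indices: all-inclusion (control),
significance filter (p < alpha ranked by |t|), Fisher-score filter, and
two wrappers -- sequential forward selection (SFS) and a genetic
algorithm (GA) -- that maximize the classifier's balanced accuracy.  The
feature budget follows the one-parameter-per-20-observations rule of
thumb: floor(n_observations / 20), 12 for a full 240-slot study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .feature_stats import IndexStats

Objective = Callable[[tuple[str, ...]], float]


@dataclass(frozen=True)
class GAParams:
    population: int = 40
    generations: int = 50
    crossover_p: float = 0.8
    mutation_p: float = 0.02  # per bit
    elitism: int = 2
    tournament: int = 3

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass(frozen=True)
class SelectionConfig:
    method: str = "all"  # all | t_filter | fisher_filter | sfs | ga
    max_features: int = 12
    alpha: float = 0.05
    seed: int = 0
    ga: GAParams = field(default_factory=GAParams)

    def __post_init__(self) -> None:
        if not 1 <= self.max_features <= 25:
            raise ValueError("max_features must be in [1, 25]")
        if self.method not in {"all", "t_filter", "fisher_filter", "sfs", "ga"}:
            raise ValueError(f"unknown selection method {self.method!r}")


@dataclass
class FeatureSubset:
    features: tuple[str, ...]
    objective_value: float | None = None
    trajectory: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)


def max_feature_budget(n_observations: int) -> int:
    """floor(n / 20); below 20 observations fall back to a single feature."""
    if n_observations < 20:
        warnings.warn("fewer than 20 observations; feature budget forced to 1")
        return 1
    return n_observations // 20


def select_all(feature_names: Sequence[str]) -> FeatureSubset:
    """All-inclusion control: every index, no budget."""
    return FeatureSubset(features=tuple(feature_names))


def select_filter_t(stats: list[IndexStats], config: SelectionConfig) -> FeatureSubset:
    """Significance filter: indices with p < alpha, ranked by |t|, capped at
    the budget.  With nothing significant, falls back to the single
    largest-|t| index (warned)."""
    signif = [s for s in stats if s.p < config.alpha]
    if not signif:
        warnings.warn("no significant indices; falling back to top-1 by |t|")
        signif = [max(stats, key=lambda s: abs(s.t))]
    ranked = sorted(signif, key=lambda s: (-abs(s.t), s.index_name))
    return FeatureSubset(
        features=tuple(s.index_name for s in ranked[: config.max_features])
    )


def select_filter_fisher(stats: list[IndexStats], config: SelectionConfig) -> FeatureSubset:
    """Fisher-score filter: top-budget indices by Fisher score, ties broken
    lexicographically by index name for determinism."""
    ranked = sorted(stats, key=lambda s: (-s.fisher, s.index_name))
    return FeatureSubset(
        features=tuple(s.index_name for s in ranked[: config.max_features])
    )


def select_sfs(
    objective: Objective,
    feature_names: Sequence[str],
    config: SelectionConfig,
) -> FeatureSubset:
    """Sequential forward selection maximizing the objective.

    Greedy growth from the empty set: at each step add the candidate
    feature with the largest objective value; stop when the budget is
    reached or no candidate strictly improves on the incumbent.  Ties go
    to the lowest feature position for determinism.
    """
    selected: list[str] = []
    best_value = -np.inf
    trajectory: list[float] = []
    remaining = list(feature_names)
    while len(selected) < config.max_features and remaining:
        scores = [objective(tuple(selected + [f])) for f in remaining]
        k = int(np.argmax(scores))  # argmax takes first (= lowest index) on ties
        if scores[k] <= best_value:
            break
        best_value = scores[k]
        selected.append(remaining.pop(k))
        trajectory.append(best_value)
    if not selected:  # objective never exceeded -inf baseline guard
        selected = [remaining[0]]
        best_value = objective(tuple(selected))
        trajectory.append(best_value)
    return FeatureSubset(
        features=tuple(selected), objective_value=best_value, trajectory=trajectory
    )


def _repair(bits: np.ndarray, budget: int, rng: np.random.Generator) -> np.ndarray:
    """Clear random set bits until the chromosome respects the budget; a
    chromosome with no set bits gets one random bit."""
    bits = bits.copy()
    on = np.flatnonzero(bits)
    if on.size == 0:
        bits[rng.integers(bits.size)] = 1
        return bits
    while on.size > budget:
        drop = rng.choice(on)
        bits[drop] = 0
        on = np.flatnonzero(bits)
    return bits


def select_ga(
    objective: Objective,
    feature_names: Sequence[str],
    config: SelectionConfig,
) -> FeatureSubset:
    """Genetic-algorithm wrapper over feature-subset bit strings.

    One bit per feature; fitness is the objective of the encoded subset
    after budget repair.  Tournament selection, uniform crossover,
    per-bit mutation, elitism; returns the best subset ever seen.
    Deterministic for a fixed seed.
    """
    params = config.ga
    rng = np.random.default_rng(config.seed)
    names = list(feature_names)
    n_bits = len(names)

    def decode(bits: np.ndarray) -> tuple[str, ...]:
        return tuple(names[i] for i in np.flatnonzero(bits))

    pop = [
        _repair((rng.random(n_bits) < 0.5).astype(np.int8), config.max_features, rng)
        for _ in range(params.population)
    ]
    cache: dict[bytes, float] = {}

    def fitness(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = objective(decode(bits))
        return cache[key]

    fits = np.array([fitness(b) for b in pop])
    best_i = int(np.argmax(fits))
    best_bits, best_fit = pop[best_i].copy(), float(fits[best_i])
    trajectory = [best_fit]

    for _ in range(params.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: params.elitism]]
        while len(new_pop) < params.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(params.population, size=params.tournament)
                parents.append(pop[max(contenders, key=lambda i: fits[i])])
            if rng.random() < params.crossover_p:
                mask = rng.random(n_bits) < 0.5
                child = np.where(mask, parents[0], parents[1]).astype(np.int8)
            else:
                child = parents[0].copy()
            flip = rng.random(n_bits) < params.mutation_p
            child[flip] = 1 - child[flip]
            child = _repair(child, config.max_features, rng)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(b) for b in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_bits = pop[gen_best].copy()
        trajectory.append(best_fit)

    return FeatureSubset(
        features=decode(best_bits), objective_value=best_fit, trajectory=trajectory
    )


def select(
    config: SelectionConfig,
    feature_names: Sequence[str],
    stats: list[IndexStats] | None = None,
    objective: Objective | None = None,
) -> FeatureSubset:
    """Dispatch to the configured regime.

    Filters need ``stats``; wrappers need ``objective``.
    """
    if config.method == "all":
        return select_all(feature_names)
    if config.method in {"t_filter", "fisher_filter"}:
        if stats is None:
            raise ValueError(f"{config.method} needs per-index statistics")
        fn = select_filter_t if config.method == "t_filter" else select_filter_fisher
        return fn(stats, config)
    if objective is None:
        raise ValueError(f"{config.method} needs an objective function")
    if config.method == "sfs":
        return select_sfs(objective, feature_names, config)
    return select_ga(objective, feature_names, config)
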