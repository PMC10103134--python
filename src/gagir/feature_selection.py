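"""μ+λ evolutionary feature selection over binary masks.

The search maximises cross-validated forest accuracy minus a soft size
penalty, which constrains the feature-to-sample ratio on small spectral
libraries where spectra carry far more bins than there are samples.  Each
generation produces λ offspring from tournament-selected parents via uniform
crossover and per-gene mutation; the next parent population is the best μ of
parents ∪ offspring (μ+λ truncation), which makes the best fitness per
generation non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from ._cart import _cv_accuracy
from .forest import ForestConfig
from .spectra import FeatureMatrix

__all__ = [
    "FeatureMask",
    "GAConfig",
    "GAResult",
    "fitness",
    "mutate",
    "crossover",
    "select_survivors",
    "evolve_masks",
    "evolve",
]


@dataclass
class FeatureMask:
    """A binary feature subset (1 = feature active) with cached fitness."""

    genes: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=bool)

    @property
    def n_active(self) -> int:
        return int(self.genes.sum())

    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.genes)


@dataclass
class GAConfig:
    """Evolutionary search hyperparameters.

    ``cv`` is either ``"loo"`` (leave-one-out fitness, matching the training
    regime) or an integer fold count for stratified k-fold, a cheaper
    surrogate for large experiment batteries.  ``size_penalty`` is the
    fitness cost per active feature.
    """

    mu: int = 40
    lambda_: int = 80
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob_per_gene: float = 0.05
    elite_count: int = 2
    tournament_size: int = 3
    size_penalty: float = 0.001
    cv: int | str = "loo"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu >= self.elite_count >= 0):
            raise ValueError("require mu >= elite_count >= 0")
        if self.lambda_ < 1:
            raise ValueError("lambda_ must be >= 1")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must lie in [0, 1]")
        if not 0 <= self.mutation_prob_per_gene <= 1:
            raise ValueError("mutation_prob_per_gene must lie in [0, 1]")


@dataclass
class GAResult:
    best_mask: FeatureMask
    fitness_history: np.ndarray  # best fitness after each generation
    selected_feature_names: list[str]


def _cv_folds(y01: np.ndarray, cv: int | str) -> list[np.ndarray]:
    """Deterministic fold assignment (stratified round-robin for k-fold)."""
    n = y01.shape[0]
    if cv == "loo":
        return [np.array([i]) for i in range(n)]
    k = int(cv)
    if k < 2:
        raise ValueError("cv fold count must be >= 2")
    fold_of = np.empty(n, dtype=int)
    for cls in np.unique(y01):
        idx = np.flatnonzero(y01 == cls)
        fold_of[idx] = np.arange(idx.size) % k
    return [np.flatnonzero(fold_of == f) for f in range(k) if np.any(fold_of == f)]


def fitness(
    mask: FeatureMask,
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    forest_config: ForestConfig | None = None,
    ga_config: GAConfig | None = None,
) -> float:
    """Cross-validated accuracy of a forest on the active features,
    minus ``size_penalty`` per active feature.  An empty mask scores 0
    without training."""
    ga_config = ga_config or GAConfig()
    forest_config = forest_config or ForestConfig(n_trees=25)
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    active = mask.active_indices()
    if active.size == 0:
        return 0.0
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    y01 = np.array([classes.index(v) for v in y.tolist()], dtype=np.int8)
    Xa = np.ascontiguousarray(X[:, active])

    folds = _cv_folds(y01, ga_config.cv)
    fold_of = np.empty(X.shape[0], dtype=np.int64)
    for f, test_idx in enumerate(folds):
        fold_of[test_idx] = f
    # the kernel's own seeded bootstrap stream: depends only on the config,
    # so equal masks always score equally (cacheable)
    accuracy = _cv_accuracy(
        Xa,
        y01,
        fold_of,
        forest_config.n_trees,
        forest_config.candidates_for(active.size),
        -1 if forest_config.max_depth is None else forest_config.max_depth,
        forest_config.min_samples_split,
        np.uint64(ga_config.seed),
    )
    return accuracy - ga_config.size_penalty * active.size


def mutate(mask: FeatureMask, prob_per_gene: float, rng: np.random.Generator) -> FeatureMask:
    """Flip each gene independently; an all-zero result is repaired by
    activating one random gene."""
    if not 0 <= prob_per_gene <= 1:
        raise ValueError("prob_per_gene must lie in [0, 1]")
    flips = rng.random(mask.genes.size) < prob_per_gene
    genes = mask.genes ^ flips
    if not genes.any():
        genes = genes.copy()
        genes[rng.integers(genes.size)] = True
    return FeatureMask(genes=genes)


def crossover(
    a: FeatureMask, b: FeatureMask, rng: np.random.Generator
) -> tuple[FeatureMask, FeatureMask]:
    """Uniform crossover: each position swaps between children with p=0.5."""
    if a.genes.size != b.genes.size:
        raise ValueError("parent masks differ in length")
    swap = rng.random(a.genes.size) < 0.5
    c1 = np.where(swap, b.genes, a.genes)
    c2 = np.where(swap, a.genes, b.genes)
    return FeatureMask(genes=c1), FeatureMask(genes=c2)


def select_survivors(
    parents: Sequence[FeatureMask], offspring: Sequence[FeatureMask], mu: int
) -> list[FeatureMask]:
    """μ+λ truncation: the best μ of parents ∪ offspring, fitness-sorted.

    Because parents compete, elites survive unchanged and the best fitness
    never decreases between generations."""
    ranked = sorted(list(parents) + list(offspring), key=lambda m: m.fitness, reverse=True)
    return ranked[:mu]


def _tournament(
    population: Sequence[FeatureMask], size: int, rng: np.random.Generator
) -> FeatureMask:
    idx = rng.integers(0, len(population), size=size)
    best = max(idx, key=lambda i: population[i].fitness)
    return population[best]


def evolve_masks(
    fitness_fn: Callable[[FeatureMask], float],
    k: int,
    config: GAConfig,
) -> tuple[FeatureMask, np.ndarray, list[FeatureMask]]:
    """Core μ+λ loop over a caller-supplied fitness function.

    Returns (best mask, per-generation best-fitness history, final
    population).  Exposed separately so the selection mechanics can be
    exercised on hand-built fitness tables.
    """
    rng = np.random.default_rng(config.seed)

    def evaluated(genes: np.ndarray) -> FeatureMask:
        m = FeatureMask(genes=genes)
        m.fitness = fitness_fn(m)
        return m

    # Initial masks are sparse: expected √k active genes, the scale at which
    # the feature-to-sample ratio stays healthy on spectral libraries whose
    # bin count far exceeds the sample count.
    def random_mask() -> FeatureMask:
        genes = rng.random(k) < max(1.0 / k, k**-0.5)
        if not genes.any():
            genes[rng.integers(k)] = True
        return evaluated(genes)

    population = sorted(
        (random_mask() for _ in range(config.mu)),
        key=lambda m: m.fitness,
        reverse=True,
    )
    history = []
    for _ in range(config.generations):
        offspring: list[FeatureMask] = []
        while len(offspring) < config.lambda_:
            p1 = _tournament(population, config.tournament_size, rng)
            p2 = _tournament(population, config.tournament_size, rng)
            if rng.random() < config.crossover_prob:
                c1, c2 = crossover(p1, p2, rng)
            else:
                c1 = FeatureMask(genes=p1.genes.copy())
                c2 = FeatureMask(genes=p2.genes.copy())
            for child in (c1, c2):
                if len(offspring) >= config.lambda_:
                    break
                child = mutate(child, config.mutation_prob_per_gene, rng)
                child.fitness = fitness_fn(child)
                offspring.append(child)
        population = select_survivors(population, offspring, config.mu)
        history.append(population[0].fitness)
    hist = np.asarray(history)
    # elitism guarantee, checked on every run
    assert hist.size == 0 or (np.diff(hist) >= 0).all(), "best fitness decreased"
    return population[0], hist, population


def evolve(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    ga_config: GAConfig | None = None,
    forest_config: ForestConfig | None = None,
) -> GAResult:
    """Run the evolutionary feature search on a labeled feature matrix."""
    ga_config = ga_config or GAConfig()
    forest_config = forest_config or ForestConfig(n_trees=25)
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples for a meaningful fitness")
    names = (
        matrix.feature_names
        if isinstance(matrix, FeatureMatrix)
        else [f"f{i}" for i in range(X.shape[1])]
    )

    cache: dict[bytes, float] = {}

    def cached_fitness(mask: FeatureMask) -> float:
        key = mask.genes.tobytes()
        if key not in cache:
            cache[key] = fitness(mask, X, labels, forest_config, ga_config)
        return cache[key]

    best, history, _ = evolve_masks(cached_fitness, X.shape[1], ga_config)
    return GAResult(
        best_mask=best,
        fitness_history=history,
        selected_feature_names=[names[i] for i in best.active_indices()],
    )
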