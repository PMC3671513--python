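"""Differential evolution (best/1/bin) over a bounded continuous domain.

Minimizes an arbitrary objective ``genes -> float``.  The engine never
repairs genes to the bounds after mutation; out-of-range values are the
objective's problem (the ellipse objective clamps at decode time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["DEConfig", "Population", "init_population", "mutate", "crossover", "select", "run_de"]


@dataclass(frozen=True)
class DEConfig:
    """Optimizer settings.  Defaults follow the calibrated parameter table
    (population 20, F = 0.25, CR = 0.80, 200 generations)."""

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 20
    scale_factor: float = 0.25
    crossover_rate: float = 0.80
    n_generations: int = 200
    seed: int = 0
    #: optional early-stop threshold on the best objective value; off by default
    stop_below: float | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValidationError("pop_size must be >= 4 (best + two distinct others != i)")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValidationError("crossover_rate must lie in [0, 1]")
        for low, high in self.bounds:
            if low > high:
                raise ValidationError(f"invalid bound ({low}, {high})")

    @property
    def n_dims(self) -> int:
        return len(self.bounds)


@dataclass
class Population:
    """Current population state: genes, their fitness values and the best index."""

    genes: np.ndarray  # (pop_size, D)
    fitnesses: np.ndarray  # (pop_size,)
    best_index: int
    generation: int = 0

    @property
    def best_genes(self) -> np.ndarray:
        return self.genes[self.best_index]

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[self.best_index])


def init_population(objective, config: DEConfig, rng: np.random.Generator) -> Population:
    """Uniform initialization ``low + U(0,1) * (high - low)`` per gene, then evaluate."""
    low = np.array([b[0] for b in config.bounds], dtype=float)
    high = np.array([b[1] for b in config.bounds], dtype=float)
    genes = low + rng.random((config.pop_size, config.n_dims)) * (high - low)
    fitnesses = np.array([objective(g) for g in genes], dtype=float)
    return Population(
        genes=genes,
        fitnesses=fitnesses,
        best_index=int(np.argmin(fitnesses)),
        generation=0,
    )


def mutate(pop: Population, i: int, config: DEConfig, rng: np.random.Generator) -> np.ndarray:
    """best/1 mutant: ``v = x_best + F * (x_r1 - x_r2)`` with r1 != r2, both != i."""
    others = [k for k in range(config.pop_size) if k != i]
    r1, r2 = rng.choice(others, size=2, replace=False)
    return pop.best_genes + config.scale_factor * (pop.genes[r1] - pop.genes[r2])


def crossover(
    mutant: np.ndarray,
    parent: np.ndarray,
    config: DEConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial crossover; dimension ``j_rand`` always inherits from the mutant."""
    d = mutant.shape[0]
    take = rng.random(d) <= config.crossover_rate
    take[rng.integers(d)] = True
    return np.where(take, mutant, parent)


def select(parent_fitness: float, trial_fitness: float) -> bool:
    """Greedy one-to-one selection: the trial survives iff its fitness is <= the parent's."""
    return trial_fitness <= parent_fitness


def run_de(objective, config: DEConfig) -> tuple[np.ndarray, float, list[float]]:
    """Run the optimizer for exactly ``n_generations`` generations.

    Returns ``(best_genes, best_fitness, history)`` where ``history`` holds the
    best fitness after initialization and after each generation; greedy
    selection makes it non-increasing.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    pop = init_population(objective, config, rng)
    history = [pop.best_fitness]
    for _ in range(config.n_generations):
        for i in range(config.pop_size):
            mutant = mutate(pop, i, config, rng)
            trial = crossover(mutant, pop.genes[i], config, rng)
            trial_fitness = float(objective(trial))
            if select(float(pop.fitnesses[i]), trial_fitness):
                pop.genes[i] = trial
                pop.fitnesses[i] = trial_fitness
                if trial_fitness <= pop.best_fitness:
                    pop.best_index = i
        pop.generation += 1
        history.append(pop.best_fitness)
        if config.stop_below is not None and pop.best_fitness < config.stop_below:
            break
    return pop.best_genes.copy(), pop.best_fitness, history
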