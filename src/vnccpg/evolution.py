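"""Real-valued genetic algorithm over the 34-entry normalised genotype.

The study reports only the search scaffolding — a genetic algorithm,
populations of 1000, 1000 generations, 1000 independent runs — so the
operators here (selection, crossover, mutation law, elitism) are explicit
configuration rather than hard-coded choices.  Defaults: tournament
selection, elitism of the top individual, uniform crossover, and per-gene
Gaussian mutation with reflection at the [-1, 1] bounds.

Scaled-down profiles are first class: the printed budget (10^9 circuit
evaluations) is cluster-scale, so `desk` and `mini` presets exist for
single-machine work and for the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np
from joblib import Parallel, delayed

from .circuit import (
    CircuitArchitecture,
    ParameterRanges,
    build_default_architecture,
    count_free_parameters,
    expand_genotype,
)
from .dynamics import IntegrationError, SimulationConfig
from .ensemble import CriteriaThresholds
from .fitness import FitnessConstants, evaluate_assay, stability_refilter

__all__ = ["EvolutionConfig", "RunResult", "run_evolution", "run_batch"]


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 200
    generations: int = 300
    elite: int = 1
    selection: str = "tournament"  # 'tournament' | 'rank'
    tournament_size: int = 3
    crossover: str = "uniform"     # 'uniform' | 'none'
    crossover_prob: float = 0.5
    mutation_sigma: float = 0.2    # on the [-1, 1] gene scale
    mutation_rate: float = 0.5     # per-gene probability
    mutation_decay: float = 0.99   # per-generation multiplicative sigma decay

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.selection not in ("tournament", "rank"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")
        if self.crossover not in ("uniform", "none"):
            raise ValueError(f"unknown crossover scheme {self.crossover!r}")

    @classmethod
    def paper_scale(cls) -> "EvolutionConfig":
        """The published search budget (cluster-scale)."""
        return cls(population_size=1000, generations=1000)

    @classmethod
    def desk_scale(cls) -> "EvolutionConfig":
        """Single-machine profile used for the scaled ensemble analyses."""
        return cls(population_size=200, generations=300)

    @classmethod
    def mini(cls) -> "EvolutionConfig":
        """Smallest useful profile (smoke tests, quick exploration)."""
        return cls(population_size=48, generations=60, mutation_decay=0.97)


@dataclass
class RunResult:
    best_genotype: np.ndarray
    best_fitness: float
    fitness_trajectory: np.ndarray  # best-so-far per generation
    seed: int
    config: EvolutionConfig
    refilter_passed: bool | None = None

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "best_fitness": float(self.best_fitness),
            "best_genotype": [float(x) for x in self.best_genotype],
            "fitness_trajectory": [float(x) for x in self.fitness_trajectory],
            "refilter_passed": self.refilter_passed,
            "config": dataclasses.asdict(self.config),
        }


def _default_objective(
    sim_config: SimulationConfig,
    constants: FitnessConstants,
    ranges: ParameterRanges,
    arch: CircuitArchitecture,
) -> Callable[[np.ndarray], float]:
    def objective(genotype: np.ndarray) -> float:
        instance = expand_genotype(genotype, ranges, arch)
        try:
            return evaluate_assay(instance, sim_config, constants).total
        except IntegrationError:
            return 0.0

    return objective


def _select_parent(rng: np.random.Generator, fitness: np.ndarray,
                   config: EvolutionConfig) -> int:
    n = len(fitness)
    if config.selection == "tournament":
        contestants = rng.integers(0, n, size=config.tournament_size)
        return int(contestants[np.argmax(fitness[contestants])])
    # rank-proportional
    order = np.argsort(fitness)  # worst..best
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    p = ranks / ranks.sum()
    return int(rng.choice(n, p=p))


def _mutate(rng: np.random.Generator, genome: np.ndarray,
            config: EvolutionConfig, sigma: float | None = None) -> np.ndarray:
    out = genome.copy()
    mask = rng.random(len(out)) < config.mutation_rate
    out[mask] += rng.normal(0.0, config.mutation_sigma if sigma is None else sigma,
                            size=mask.sum())
    # reflect at the [-1, 1] bounds (triangle-wave fold)
    out = 1.0 - np.abs((out + 1.0) % 4.0 - 2.0)
    return out


def run_evolution(
    config: EvolutionConfig | None = None,
    seed: int = 0,
    objective: Callable[[np.ndarray], float] | None = None,
    sim_config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    ranges: ParameterRanges | None = None,
    arch: CircuitArchitecture | None = None,
    genome_length: int | None = None,
) -> RunResult:
    """One seeded, deterministic GA run maximising the assay fitness.

    A custom `objective` (any genotype -> float) replaces the locomotion
    assay, e.g. for optimizer sanity checks on analytic surrogates.
    """
    config = config or EvolutionConfig()
    arch = arch or build_default_architecture()
    ranges = ranges or ParameterRanges()
    if objective is None:
        objective = _default_objective(sim_config or SimulationConfig(),
                                       constants, ranges, arch)
        genome_length = count_free_parameters(arch)["total"]
    elif genome_length is None:
        genome_length = count_free_parameters(arch)["total"]

    rng = np.random.default_rng(seed)
    pop = rng.uniform(-1.0, 1.0, size=(config.population_size, genome_length))
    fitness = np.array([objective(g) for g in pop])

    best_idx = int(np.argmax(fitness))
    best_genome = pop[best_idx].copy()
    best_fit = float(fitness[best_idx])
    trajectory = np.empty(config.generations)

    sigma = config.mutation_sigma
    for gen in range(config.generations):
        new_pop = np.empty_like(pop)
        # elitism: carry over the current top individuals unchanged
        elite_order = np.argsort(fitness)[::-1][:config.elite]
        for k, idx in enumerate(elite_order):
            new_pop[k] = pop[idx]
        for k in range(config.elite, config.population_size):
            i = _select_parent(rng, fitness, config)
            child = pop[i]
            if config.crossover == "uniform" and rng.random() < config.crossover_prob:
                j = _select_parent(rng, fitness, config)
                take = rng.random(genome_length) < 0.5
                child = np.where(take, pop[i], pop[j])
            new_pop[k] = _mutate(rng, child, config, sigma)
        sigma *= config.mutation_decay
        pop = new_pop
        fitness = np.array([objective(g) for g in pop])
        gen_best = int(np.argmax(fitness))
        if fitness[gen_best] > best_fit:
            best_fit = float(fitness[gen_best])
            best_genome = pop[gen_best].copy()
        trajectory[gen] = best_fit

    return RunResult(best_genotype=best_genome, best_fitness=best_fit,
                     fitness_trajectory=trajectory, seed=seed, config=config)


def run_batch(
    config: EvolutionConfig | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    n_jobs: int = 1,
    refilter: bool = True,
    sim_config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    thresholds: CriteriaThresholds | None = None,
) -> list[RunResult]:
    """Independent seeded runs (the ensemble-of-runs design).

    Per-run seeds are drawn once from `base_seed`, so the batch is
    reproducible as a set and order-independent.  With `refilter`, each
    best-of-run circuit is re-simulated on the long horizon and its
    `refilter_passed` flag records whether the criteria survive (damped
    oscillators fail here).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    config = config or EvolutionConfig()
    seed_rng = np.random.default_rng(base_seed)
    seeds = []
    seen = set()
    while len(seeds) < n_runs:  # distinct seeds, reproducibly
        s = int(seed_rng.integers(0, 2**31 - 1))
        if s not in seen:
            seen.add(s)
            seeds.append(s)

    results = Parallel(n_jobs=n_jobs)(
        delayed(run_evolution)(config, seed=s, sim_config=sim_config,
                               constants=constants)
        for s in seeds
    )

    if refilter:
        for res in results:
            instance = expand_genotype(res.best_genotype)
            try:
                res.refilter_passed = stability_refilter(
                    instance, sim_config, constants, thresholds).passed
            except IntegrationError:
                res.refilter_passed = False
    return results
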