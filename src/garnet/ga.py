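"""Phase I: repeated short-run genetic-algorithm "virtual evolution".

Each of the ``m`` cycles evolves a population of mutation sets for
``n`` generations and reports the best individual of the final
generation (the *lastgen-elite*), always expressed relative to the
original template.  A genome is a position-wise choice vector — each
candidate position holds either the wild-type residue or exactly one
admissible substitution — so the one-mutation-per-position rule is
structural.

In ``reu+hisol`` mode the first ⌈m/2⌉ cycles optimize the structure
energy and the remainder the HiSol score.  With ``chain_cycles`` each
cycle seeds its population from the previous elite, so mutations
accumulate over the m cycles; without it every cycle restarts from the
template.  Per-cycle RNG streams are derived from (seed, cycle index),
making any cycle reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .mutations import Mutation, MutationSpace

FitnessFn = Callable[[frozenset], float]


class GAError(ValueError):
    pass


@dataclass
class GAConfig:
    m: int = 10                      # cycles
    n: int = 10                      # generations per cycle
    k: int = 10                      # target mutation count (used downstream)
    fitness_mode: str = "reu+hisol"
    population_size: int = 50
    genome_mutation_rate: float = 0.02
    crossover_rate: float = 0.7
    tournament_size: int = 3
    elitism_count: int = 2
    max_active_mutations: int | None = None  # default 3k
    chain_cycles: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1 or self.k < 1:
            raise GAError("m, n and k must all be >= 1")
        if not 0 < self.genome_mutation_rate < 1:
            raise GAError("genome_mutation_rate must be in (0, 1)")
        if not 0 <= self.crossover_rate <= 1:
            raise GAError("crossover_rate must be in [0, 1]")
        if self.elitism_count < 1 or self.elitism_count >= self.population_size:
            raise GAError("need 1 <= elitism_count < population_size")
        if self.max_active_mutations is None:
            self.max_active_mutations = 3 * self.k


@dataclass(frozen=True)
class CycleResult:
    cycle_index: int
    lastgen_elite: frozenset  # of Mutation, relative to the ORIGINAL template
    trajectory: tuple[float, ...]  # per-generation elite score, length n
    fitness_mode: str


# a genome is a dict position -> Mutation (absent position = wild type)
Genome = dict


def _genome_key(genome: Genome) -> frozenset:
    return frozenset(genome.values())


def memoize_fitness(fn: FitnessFn) -> FitnessFn:
    """Cache a fitness callable by mutation set (safe for pure scores)."""
    cache: dict[frozenset, float] = {}

    def wrapped(mutations: frozenset) -> float:
        if mutations not in cache:
            cache[mutations] = fn(mutations)
        return cache[mutations]

    return wrapped


def _repair(genome: Genome, max_active: int, rng: np.random.Generator) -> Genome:
    """Randomly deactivate excess mutations beyond the size cap."""
    if len(genome) <= max_active:
        return genome
    positions = sorted(genome)
    drop = rng.choice(len(positions), size=len(genome) - max_active, replace=False)
    for idx in drop:
        del genome[positions[idx]]
    return genome


def _tournament(
    population: Sequence[Genome],
    scores: Sequence[float],
    size: int,
    rng: np.random.Generator,
) -> Genome:
    picks = rng.integers(0, len(population), size=size)
    best = min(picks, key=lambda i: (scores[i], i))
    return dict(population[best])


def run_generation(
    population: list[Genome],
    fitness: FitnessFn,
    rng: np.random.Generator,
    config: GAConfig,
    space: MutationSpace,
) -> list[Genome]:
    """One generation: elitism, tournament selection, crossover, mutation.

    The best ``elitism_count`` genomes are copied unchanged, so the
    elite score can never worsen between generations.  Offspring come
    from tournament selection, position-wise uniform crossover, and a
    per-position mutation step that resamples the position uniformly
    among {wild type} ∪ candidates; the active-mutation cap is repaired
    by random deactivation.
    """
    if len(population) < 2:
        raise GAError("population must hold at least 2 genomes")
    scores = [fitness(_genome_key(g)) for g in population]
    order = sorted(range(len(population)), key=lambda i: (scores[i], i))
    next_pop: list[Genome] = [dict(population[i]) for i in order[: config.elitism_count]]
    by_position = space.by_position
    positions = space.positions
    n_pos = len(positions)
    while len(next_pop) < len(population):
        p1 = _tournament(population, scores, config.tournament_size, rng)
        if rng.random() < config.crossover_rate:
            p2 = _tournament(population, scores, config.tournament_size, rng)
            take_p2 = rng.random(n_pos) < 0.5
            child: Genome = {}
            for pos, from_p2 in zip(positions, take_p2):
                donor = p2 if from_p2 else p1
                if pos in donor:
                    child[pos] = donor[pos]
        else:
            child = p1
        hit = np.flatnonzero(rng.random(n_pos) < config.genome_mutation_rate)
        for idx in hit:
            pos = positions[idx]
            options = by_position[pos]
            pick = rng.integers(0, len(options) + 1)  # index len(options) = wild type
            if pick == len(options):
                child.pop(pos, None)
            else:
                child[pos] = options[pick]
        child = _repair(child, config.max_active_mutations, rng)
        next_pop.append(child)
    return next_pop


def _random_genome(
    space: MutationSpace, k: int, rng: np.random.Generator, max_active: int
) -> Genome:
    by_position = space.by_position
    positions = space.positions
    rate = min(1.0, k / max(1, len(positions)))
    genome: Genome = {}
    active = np.flatnonzero(rng.random(len(positions)) < rate)
    for idx in active:
        pos = positions[idx]
        options = by_position[pos]
        genome[pos] = options[rng.integers(0, len(options))]
    return _repair(genome, max_active, rng)


def run_cycle(
    space: MutationSpace,
    start_mutations: frozenset,
    n: int,
    fitness: FitnessFn,
    rng: np.random.Generator,
    config: GAConfig,
    fitness_mode: str,
    cycle_index: int = 0,
    initial_population: list[Genome] | None = None,
) -> CycleResult:
    """Run n generations and return the final elite vs the original template."""
    if not space.candidates:
        raise GAError("mutation space is empty")
    if initial_population is None:
        start_genome: Genome = {m.position: m for m in start_mutations}
        population = [dict(start_genome)]
        while len(population) < config.population_size:
            population.append(
                _random_genome(space, config.k, rng, config.max_active_mutations)
            )
    else:
        population = [dict(g) for g in initial_population]
    trajectory = []
    for _ in range(n):
        population = run_generation(population, fitness, rng, config, space)
        scores = [fitness(_genome_key(g)) for g in population]
        trajectory.append(min(scores))
    best = min(range(len(population)), key=lambda i: (scores[i], i))
    return CycleResult(
        cycle_index=cycle_index,
        lastgen_elite=_genome_key(population[best]),
        trajectory=tuple(trajectory),
        fitness_mode=fitness_mode,
    )


def cycle_modes(m: int, fitness_mode: str) -> list[str]:
    """Per-cycle fitness assignment; combined mode splits cycles half/half."""
    if fitness_mode == "reu+hisol":
        n_reu = (m + 1) // 2
        return ["reu"] * n_reu + ["hisol"] * (m - n_reu)
    return [fitness_mode] * m


def cycle_rng(seed: int, cycle_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, cycle_index)))


def run_phase1(
    space: MutationSpace,
    config: GAConfig,
    fitness_for_mode: Callable[[str], FitnessFn],
) -> list[CycleResult]:
    """m cycles of virtual evolution, each recorded as its lastgen-elite.

    ``fitness_for_mode`` maps 'reu' or 'hisol' to a score callable over
    mutation sets (lower is better).
    """
    modes = cycle_modes(config.m, config.fitness_mode)
    evaluators = {mode: fitness_for_mode(mode) for mode in dict.fromkeys(modes)}
    results: list[CycleResult] = []
    start: frozenset = frozenset()
    for c, mode in enumerate(modes):
        rng = cycle_rng(config.seed, c)
        res = run_cycle(
            space,
            start,
            config.n,
            evaluators[mode],
            rng,
            config,
            fitness_mode=mode,
            cycle_index=c,
        )
        results.append(res)
        if config.chain_cycles:
            start = res.lastgen_elite
    return results
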