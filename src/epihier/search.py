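"""Heuristic discovery of function combinations with strong three-way epistasis.

The 25^6 combinations of chain functions are far too many to enumerate, so
two stochastic searches are provided. Candidates are encoded as 30-bit
strings (6 slots x 5 bits, each field decoded modulo 25 to a function
index). Fitness of a candidate is the pure three-way interaction
information of (TF1, TF2, enhancer) with status, measured on a single
case-control dataset simulated from the decoded model — so fitness is
stochastic, exactly as when each candidate model is judged by one simulated
study. Models whose liability distribution is degenerate (a single point,
so no case/control split exists) or which cannot supply the requested
numbers of cases and controls receive fitness -inf.

``random_search`` draws and evaluates n independent candidates.
``ga_search`` runs a generational genetic algorithm (tournament-2
selection, uniform crossover, per-bit mutation, elitism), evaluating at
most population_size x generations candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import threeway_ig
from .model import HierarchyModel
from .simulate import simulate_case_control
from .functions import FUNCTION_NAMES

__all__ = [
    "BITS_PER_SLOT",
    "N_SLOTS",
    "SearchIndividual",
    "SearchConfig",
    "decode_bits",
    "encode_functions",
    "fitness",
    "random_search",
    "ga_search",
]

BITS_PER_SLOT = 5
N_SLOTS = 6
_N_BITS = BITS_PER_SLOT * N_SLOTS


def decode_bits(bits) -> tuple[str, ...]:
    """Decode a 30-bit string into six function names (each 5-bit field is
    taken modulo 25, so every bitstring is a valid model)."""
    bits = tuple(int(b) for b in bits)
    if len(bits) != _N_BITS or any(b not in (0, 1) for b in bits):
        raise ValueError(f"expected {_N_BITS} bits of 0/1")
    names = []
    for slot in range(N_SLOTS):
        chunk = bits[slot * BITS_PER_SLOT : (slot + 1) * BITS_PER_SLOT]
        value = 0
        for b in chunk:
            value = value * 2 + b
        names.append(FUNCTION_NAMES[value % len(FUNCTION_NAMES)])
    return tuple(names)


def encode_functions(functions) -> tuple[int, ...]:
    """Encode six function names into the canonical 30-bit string."""
    bits: list[int] = []
    for name in functions:
        idx = FUNCTION_NAMES.index(name)
        bits.extend(int(c) for c in format(idx, f"0{BITS_PER_SLOT}b"))
    return tuple(bits)


@dataclass(frozen=True)
class SearchIndividual:
    """An evaluated candidate: its encoding, decoded functions, realized
    fitness (three-way IG on its simulated dataset) and provenance."""

    bits: tuple[int, ...]
    functions: tuple[str, ...]
    fitness: float
    generation: int = 0


@dataclass
class SearchConfig:
    """Search settings; the fitness dataset parameters default to the study
    conditions (1,000/1,000 sampled from 100,000 at prevalence 0.10)."""

    population_size: int = 100
    generations: int = 100
    mutation_rate: float = 1.0 / _N_BITS
    crossover_rate: float = 0.9
    elitism: int = 1
    tournament_size: int = 2
    prevalence: float = 0.10
    pop_size: int = 100_000
    n_cases: int = 1000
    n_controls: int = 1000

    def __post_init__(self):
        if self.population_size < 2 or self.generations < 1:
            raise ValueError("population_size must be >= 2 and generations >= 1")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism must be in [0, population_size]")

    @property
    def budget(self) -> int:
        return self.population_size * self.generations


def fitness(functions, config: SearchConfig, seed) -> float:
    """Three-way interaction information of (TF1, TF2, enhancer) on one
    dataset simulated from the decoded model; -inf for models that cannot
    produce a case-control split."""
    model = HierarchyModel(functions=tuple(functions))
    try:
        dataset, _ = simulate_case_control(
            model,
            prevalence=config.prevalence,
            pop_size=config.pop_size,
            n_cases=config.n_cases,
            n_controls=config.n_controls,
            seed=seed,
        )
    except ValueError:
        # degenerate liability (no threshold) or too few cases/controls
        return float("-inf")
    return threeway_ig(dataset, "TF1", "TF2", "enhancer").threeway_ig


def _evaluate(bits, config, rng, generation) -> SearchIndividual:
    functions = decode_bits(bits)
    # fresh sub-seed per evaluation: fitness is intentionally stochastic
    sub = int(rng.integers(0, 2**31 - 1))
    return SearchIndividual(
        bits=tuple(bits),
        functions=functions,
        fitness=fitness(functions, config, sub),
        generation=generation,
    )


def random_search(n: int, config: SearchConfig, seed) -> list[SearchIndividual]:
    """Evaluate ``n`` uniformly random encodings; returns them ranked by
    fitness, best first. Deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    individuals = [
        _evaluate(rng.integers(0, 2, size=_N_BITS), config, rng, 0) for _ in range(n)
    ]
    return sorted(individuals, key=lambda ind: ind.fitness, reverse=True)


def ga_search(
    config: SearchConfig, seed
) -> tuple[list[SearchIndividual], list[float]]:
    """Generational GA over function combinations.

    Returns (hall of fame: every evaluated individual ranked by fitness,
    best first; trace: best fitness seen up to each generation — with
    elitism >= 1 the trace is non-decreasing). At most
    ``population_size * generations`` fitness evaluations are performed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = config.population_size
    population = [
        _evaluate(rng.integers(0, 2, size=_N_BITS), config, rng, 0) for _ in range(m)
    ]
    hall_of_fame = list(population)
    best = max(population, key=lambda ind: ind.fitness)
    trace = [best.fitness]

    def tournament() -> SearchIndividual:
        picks = [population[int(rng.integers(0, m))] for _ in range(config.tournament_size)]
        return max(picks, key=lambda ind: ind.fitness)

    for gen in range(1, config.generations):
        elites = sorted(population, key=lambda ind: ind.fitness, reverse=True)[
            : config.elitism
        ]
        offspring: list[SearchIndividual] = list(elites)
        while len(offspring) < m:
            p1 = np.array(tournament().bits)
            p2 = np.array(tournament().bits)
            if rng.random() < config.crossover_rate:
                mask = rng.integers(0, 2, size=_N_BITS).astype(bool)
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(_N_BITS) < config.mutation_rate
            child = np.where(flip, 1 - child, child)
            offspring.append(_evaluate(child, config, rng, gen))
        population = offspring
        hall_of_fame.extend(population[config.elitism :])
        gen_best = max(population, key=lambda ind: ind.fitness)
        if gen_best.fitness > best.fitness:
            best = gen_best
        trace.append(best.fitness)

    ranked = sorted(hall_of_fame, key=lambda ind: ind.fitness, reverse=True)
    return ranked, trace
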