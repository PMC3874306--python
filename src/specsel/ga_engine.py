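"""Generational genetic algorithm over subsets of variable indices.

Individuals are ordered sequences of distinct 1-based variable indices,
of fixed or per-individual variable length.  Operators: roulette-wheel
selection on minimized fitness, uniform crossover (left-aligned, length
preserving), uniform gene mutation, generational replacement with
single-individual elitism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, SpecselError

# Additive floor for roulette scores; an all-equal generation degrades to
# uniform selection instead of a zero wheel.
_SCORE_DELTA = 1e-12


@dataclass(frozen=True)
class Individual:
    """An ordered subset of distinct variable indices (the genes)."""

    genes: tuple[int, ...]

    def __post_init__(self) -> None:
        genes = tuple(int(g) for g in self.genes)
        if len(genes) == 0:
            raise ConfigError("individual must carry at least one gene")
        if len(set(genes)) != len(genes):
            raise ConfigError(f"duplicate genes in individual {genes}")
        if any(g < 1 for g in genes):
            raise ConfigError(f"gene indices must be >= 1; got {genes}")
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def key(self) -> tuple[int, ...]:
        """Order-insensitive identity of the subset."""
        return tuple(sorted(self.genes))


@dataclass
class Population:
    individuals: list[Individual]
    generation_index: int = 0


@dataclass(frozen=True)
class LengthMode:
    """fixed(L) or variable(min, max) chromosome length."""

    kind: str
    fixed: int | None = None
    min_len: int | None = None
    max_len: int | None = None

    @classmethod
    def fixed_length(cls, L: int) -> "LengthMode":
        if L < 1:
            raise ConfigError("fixed length must be >= 1")
        return cls("fixed", fixed=L)

    @classmethod
    def variable_length(cls, min_len: int, max_len: int) -> "LengthMode":
        if not 1 <= min_len <= max_len:
            raise ConfigError("variable lengths need 1 <= min <= max")
        return cls("variable", min_len=min_len, max_len=max_len)

    @property
    def max_needed(self) -> int:
        return self.fixed if self.kind == "fixed" else self.max_len


@dataclass
class GAConfig:
    """Run configuration; defaults follow the reference setup
    (100 individuals, 100 generations, 90% uniform crossover, 10% uniform
    mutation, roulette selection, simple generational GA)."""

    population_size: int = 100
    max_generations: int = 100
    crossover_rate: float = 0.90
    mutation_rate: float = 0.10
    selection: str = "roulette"
    crossover: str = "uniform"
    mutation: str = "uniform"
    length_mode: LengthMode = field(default_factory=lambda: LengthMode.fixed_length(2))
    elitism: bool = True
    rng_seed: int = 0
    convergence_threshold: float = 0.95
    stagnation_window: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        for name in ("crossover_rate", "mutation_rate", "convergence_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]; got {v}")
        if self.selection != "roulette":
            raise ConfigError(f"unsupported selection {self.selection!r}")
        if self.crossover != "uniform":
            raise ConfigError(f"unsupported crossover {self.crossover!r}")
        if self.mutation != "uniform":
            raise ConfigError(f"unsupported mutation {self.mutation!r}")
        if self.stagnation_window is not None and self.stagnation_window < 1:
            raise ConfigError("stagnation_window must be >= 1 or None")


@dataclass
class GAResult:
    best_individuals: list[tuple[Individual, float]]
    fitness_trace: list[tuple[float, float]]  # per generation (best, mean)
    termination_reason: str
    seed: int

    @property
    def best(self) -> tuple[Individual, float]:
        return self.best_individuals[0]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    init_ss, sel_ss, cx_ss, mut_ss = np.random.SeedSequence(seed).spawn(4)
    return {
        "init": np.random.default_rng(init_ss),
        "selection": np.random.default_rng(sel_ss),
        "crossover": np.random.default_rng(cx_ss),
        "mutation": np.random.default_rng(mut_ss),
    }


def _random_individual(length: int, V: int, rng: np.random.Generator) -> Individual:
    # redraw whole combinations until all genes are distinct, mirroring the
    # rejection-style initialization
    while True:
        genes = tuple(int(g) for g in rng.integers(1, V + 1, size=length))
        if len(set(genes)) == length:
            return Individual(genes)


def init_population(config: GAConfig, V: int, rng: np.random.Generator | None = None) -> Population:
    """Random initial population; lengths per ``config.length_mode``."""
    mode = config.length_mode
    if mode.max_needed > V:
        raise ConfigError(
            f"chromosome length {mode.max_needed} exceeds variable count {V}"
        )
    rng = rng if rng is not None else _substreams(config.rng_seed)["init"]
    individuals = []
    for _ in range(config.population_size):
        if mode.kind == "fixed":
            length = mode.fixed
        else:
            length = int(rng.integers(mode.min_len, mode.max_len + 1))
        individuals.append(_random_individual(length, V, rng))
    return Population(individuals, generation_index=0)


def roulette_select(
    pop: Population, scores: Sequence[float], rng: np.random.Generator
) -> Individual:
    """Draw one individual with probability proportional to its score.

    Scores must be non-negative; an all-zero wheel falls back to a uniform
    draw.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) != len(pop.individuals):
        raise ConfigError("scores and population size differ")
    if np.any(scores < 0):
        raise ConfigError("roulette scores must be non-negative")
    total = float(scores.sum())
    if total == 0.0:
        idx = int(rng.integers(0, len(scores)))
        return pop.individuals[idx]
    cum = np.cumsum(scores)
    r = rng.random() * total
    idx = int(np.searchsorted(cum, r, side="right"))
    idx = min(idx, len(scores) - 1)
    return pop.individuals[idx]


def _repair(genes: list[int], V: int, rng: np.random.Generator) -> list[int]:
    """Redraw duplicate genes uniformly from indices absent from the child."""
    seen: set[int] = set()
    dup_positions = []
    for i, g in enumerate(genes):
        if g in seen:
            dup_positions.append(i)
        else:
            seen.add(g)
    for i in dup_positions:
        pool = np.array(sorted(set(range(1, V + 1)) - seen), dtype=int)
        if pool.size == 0:
            raise ConfigError("cannot repair duplicates: no unused indices left")
        g = int(pool[int(rng.integers(0, pool.size))])
        genes[i] = g
        seen.add(g)
    return genes


def uniform_crossover(
    p1: Individual, p2: Individual, rng: np.random.Generator, V: int
) -> tuple[Individual, Individual]:
    """Positionwise uniform mix of two parents, preserving both lengths.

    For each position up to the shorter length, child 1 takes the gene from
    either parent with probability 1/2 and child 2 takes the complementary
    gene.  Tail positions of the longer parent go to the same-length child.
    Duplicates introduced by mixing are repaired by redrawing uniformly
    from indices the child does not already carry.
    """
    g1, g2 = list(p1.genes), list(p2.genes)
    n = min(len(g1), len(g2))
    c1 = list(g1)
    c2 = list(g2)
    for i in range(n):
        if rng.random() < 0.5:
            c1[i], c2[i] = g2[i], g1[i]
    c1 = _repair(c1, V, rng)
    c2 = _repair(c2, V, rng)
    return Individual(tuple(c1)), Individual(tuple(c2))


def uniform_mutate(
    ind: Individual, mutation_rate: float, V: int, rng: np.random.Generator
) -> Individual:
    """Independently replace each gene with probability ``mutation_rate`` by
    an index drawn uniformly from those the individual does not carry."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ConfigError("mutation_rate must be in [0, 1]")
    genes = list(ind.genes)
    if V == len(genes):
        # no replacement candidates exist
        return ind
    current = set(genes)
    for i in range(len(genes)):
        if rng.random() < mutation_rate:
            pool = np.array(sorted(set(range(1, V + 1)) - current), dtype=int)
            g = int(pool[int(rng.integers(0, pool.size))])
            current.discard(genes[i])
            current.add(g)
            genes[i] = g
    return Individual(tuple(genes))


def check_convergence(pop: Population, threshold: float) -> bool:
    """True when at every gene position a fraction >= ``threshold`` of the
    population carries the same index.  Variable-length populations never
    report convergence."""
    lengths = {len(ind) for ind in pop.individuals}
    if len(lengths) != 1:
        return False
    n = len(pop.individuals)
    length = lengths.pop()
    for pos in range(length):
        values = [ind.genes[pos] for ind in pop.individuals]
        _, counts = np.unique(np.array(values), return_counts=True)
        if counts.max() / n < threshold:
            return False
    return True


def fitness_to_scores(fitnesses: Sequence[float]) -> np.ndarray:
    """Map minimized fitness onto non-negative roulette scores:
    score_i = (worst - fitness_i) + delta."""
    f = np.asarray(fitnesses, dtype=np.float64)
    return (f.max() - f) + _SCORE_DELTA


def evolve(
    config: GAConfig,
    V: int,
    fitness_fn: Callable[[Individual], float],
) -> GAResult:
    """Run the generational loop and return the ranked distinct subsets.

    Fitness is minimized.  The loop is bitwise repeatable for a fixed
    ``config.rng_seed``: the master seed derives independent substreams for
    initialization, selection, crossover and mutation.
    """
    rngs = _substreams(config.rng_seed)
    pop = init_population(config, V, rng=rngs["init"])

    def _evaluate(individuals: list[Individual]) -> list[float]:
        out = []
        for ind in individuals:
            try:
                out.append(float(fitness_fn(ind)))
            except Exception as exc:  # noqa: BLE001 - context then re-raise
                raise SpecselError(
                    f"fitness evaluation failed for genes {ind.genes}: {exc}"
                ) from exc
        return out

    fits = _evaluate(pop.individuals)
    archive: dict[tuple[int, ...], tuple[Individual, float]] = {}
    trace: list[tuple[float, float]] = []
    reason = "max_generations"
    stagnant = 0
    prev_best = np.inf

    for gen in range(config.max_generations + 1):
        pop.generation_index = gen
        best_idx = int(np.argmin(fits))
        best_fit = fits[best_idx]
        trace.append((best_fit, float(np.mean(fits))))
        for ind, f in zip(pop.individuals, fits):
            key = ind.key()
            if key not in archive or f < archive[key][1]:
                archive[key] = (ind, f)

        if check_convergence(pop, config.convergence_threshold):
            reason = "converged"
            break
        if config.stagnation_window is not None:
            if prev_best - best_fit > _SCORE_DELTA:
                stagnant = 0
            else:
                stagnant += 1
            if stagnant >= config.stagnation_window:
                reason = "stagnated"
                break
        prev_best = min(prev_best, best_fit)
        if gen == config.max_generations:
            reason = "max_generations"
            break

        scores = fitness_to_scores(fits)
        children: list[Individual] = []
        while len(children) < config.population_size:
            pa = roulette_select(pop, scores, rngs["selection"])
            pb = roulette_select(pop, scores, rngs["selection"])
            if rngs["crossover"].random() < config.crossover_rate:
                ca, cb = uniform_crossover(pa, pb, rngs["crossover"], V)
            else:
                ca, cb = pa, pb
            ca = uniform_mutate(ca, config.mutation_rate, V, rngs["mutation"])
            cb = uniform_mutate(cb, config.mutation_rate, V, rngs["mutation"])
            children.extend([ca, cb])
        children = children[: config.population_size]
        child_fits = _evaluate(children)

        if config.elitism:
            worst_child = int(np.argmax(child_fits))
            children[worst_child] = pop.individuals[best_idx]
            child_fits[worst_child] = best_fit

        pop = Population(children, generation_index=gen + 1)
        fits = child_fits

    ranked = sorted(archive.values(), key=lambda t: (t[1], t[0].key()))
    return GAResult(
        best_individuals=ranked,
        fitness_trace=trace,
        termination_reason=reason,
        seed=config.rng_seed,
    )
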