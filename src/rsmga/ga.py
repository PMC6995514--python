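"""Real-coded genetic algorithm over a box, with the classical operator
suite: rank fitness scaling (1/sqrt(rank)), stochastic-uniform selection,
scattered (uniform-mask) crossover, shrinking Gaussian mutation, elitism,
and optional ring-forward migration between subpopulations.

The public API speaks maximization; internally the engine minimizes the
negated objective (the convention of the classical solver this operator
suite comes from), which is why the stall test compares the *decrease* of
the internal objective against ``function_tolerance``.

With ``crossover_fraction = 1`` every non-elite child is a crossover child
and no new gene values are ever created: the search recombines the initial
uniform draws.  That is the faithful replication setting; for general use a
fraction below 1 keeps Gaussian mutation active and allows local refinement.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from rsmga.doe import InvalidParameterError

__all__ = [
    "GAConfig",
    "GAResult",
    "initialize_population",
    "rank_scale",
    "select_stochastic_uniform",
    "crossover_scattered",
    "mutate_gaussian",
    "step_generation",
    "run_ga",
]


@dataclass
class GAConfig:
    """Full parameterization of the evolutionary search.

    Defaults replicate the study configuration: population 200, elite count
    2, crossover fraction 1, 100 generations, stall limits of 50 generations
    and 20 seconds, single population (migration settings are then inert).
    ``bounds`` and ``init_ranges`` are (k, 2) arrays of per-gene
    [low, high]; if ``init_ranges`` is omitted it defaults to ``bounds``.
    ``fitness_limit`` is on the maximization scale: the run stops once the
    best fitness reaches it (default +inf, never).
    """

    bounds: np.ndarray = None
    init_ranges: np.ndarray = None
    population_size: int = 200
    elite_count: int = 2
    crossover_fraction: float = 1.0
    generations: int = 100
    stall_generations: int = 50
    stall_time_seconds: float = 20.0
    time_limit_seconds: float = np.inf
    fitness_limit: float = np.inf
    migration_interval: int = 20
    migration_fraction: float = 0.2
    migration_direction: str = "forward"
    n_subpopulations: int = 1
    mutation_scale: float = 1.0
    mutation_shrink: float = 1.0
    function_tolerance: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.bounds is None:
            raise InvalidParameterError("bounds are required")
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.init_ranges is None:
            self.init_ranges = self.bounds.copy()
        self.init_ranges = np.atleast_2d(np.asarray(self.init_ranges, dtype=float))
        if self.bounds.shape != self.init_ranges.shape or self.bounds.shape[1] != 2:
            raise InvalidParameterError("bounds and init_ranges must be (k, 2)")
        if np.any(self.bounds[:, 0] > self.bounds[:, 1]) or np.any(
            self.init_ranges[:, 0] > self.init_ranges[:, 1]
        ):
            raise InvalidParameterError("each [low, high] must satisfy low <= high")
        if not (0 <= self.elite_count < self.population_size):
            raise InvalidParameterError("need 0 <= elite_count < population_size")
        if not (0.0 <= self.crossover_fraction <= 1.0):
            raise InvalidParameterError("crossover_fraction must lie in [0, 1]")
        if self.migration_direction not in ("forward", "both"):
            raise InvalidParameterError("migration_direction must be 'forward' or 'both'")
        if self.n_subpopulations < 1:
            raise InvalidParameterError("n_subpopulations must be >= 1")

    @property
    def n_genes(self) -> int:
        return self.bounds.shape[0]


@dataclass
class GAResult:
    """Outcome of one GA run (maximization scale throughout)."""

    best_genes: np.ndarray
    best_fitness: float
    generations_run: int
    history: pd.DataFrame  # columns: generation, best, mean
    termination_reason: str


def initialize_population(config: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform initial population: (population_size, k), gene i i.i.d.
    uniform on init_ranges[i]."""
    lo, hi = config.init_ranges[:, 0], config.init_ranges[:, 1]
    return rng.uniform(lo, hi, size=(config.population_size, config.n_genes))


def rank_scale(fitnesses, n_parents: int, minimize: bool = False) -> np.ndarray:
    """Rank-based selection expectations.

    The individual of fitness rank r (1 = best) gets raw score 1/sqrt(r);
    scores are rescaled so they sum to ``n_parents``.  Ties are broken by
    stable input order.  ``minimize=True`` ranks ascending (internal engine
    convention); the default ranks descending (maximization).
    """
    f = np.asarray(fitnesses, dtype=float)
    if f.size == 0:
        raise InvalidParameterError("fitnesses must be nonempty")
    key = f if minimize else -f
    order = np.argsort(key, kind="stable")
    raw = np.empty(f.size)
    raw[order] = 1.0 / np.sqrt(np.arange(1, f.size + 1))
    return raw * (n_parents / raw.sum())


def select_stochastic_uniform(
    expectations, n_parents: int, rng: np.random.Generator
) -> np.ndarray:
    """Stochastic-uniform (single-spin, equally spaced pointer) selection.

    The expectations are laid on a line; one uniform start in [0, step) and
    pointers at equal steps pick exactly ``n_parents`` indices, so each
    individual is chosen between floor and ceil of its expectation.
    """
    e = np.asarray(expectations, dtype=float)
    cum = np.cumsum(e)
    step = cum[-1] / n_parents
    pointers = step * rng.uniform() + step * np.arange(n_parents)
    return np.searchsorted(cum, pointers, side="right").clip(max=e.size - 1)


def crossover_scattered(
    parent_a: np.ndarray, parent_b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform crossover: an independent fair binary mask per gene picks the
    donor parent."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("parents must have equal gene lengths")
    mask = rng.random(a.shape) < 0.5
    return np.where(mask, a, b)


def mutation_sd(config: GAConfig, generation: int) -> np.ndarray:
    """Per-gene Gaussian mutation SD at a given generation.

    SD = mutation_scale * init-range width * (1 - shrink * gen/generations),
    floored at zero.
    """
    width = config.init_ranges[:, 1] - config.init_ranges[:, 0]
    frac = 1.0 - config.mutation_shrink * generation / max(config.generations, 1)
    return config.mutation_scale * width * max(frac, 0.0)


def mutate_gaussian(
    ind: np.ndarray, generation: int, config: GAConfig, rng: np.random.Generator
) -> np.ndarray:
    """Add zero-mean Gaussian noise with the shrink schedule; clip to bounds."""
    sd = mutation_sd(config, generation)
    child = np.asarray(ind, dtype=float) + rng.standard_normal(config.n_genes) * sd
    return np.clip(child, config.bounds[:, 0], config.bounds[:, 1])


def _child_counts(config: GAConfig) -> tuple[int, int]:
    n_children = config.population_size - config.elite_count
    n_cross = int(round(config.crossover_fraction * n_children))
    return n_cross, n_children - n_cross


def _next_generation(
    population: np.ndarray,
    internal_fitness: np.ndarray,
    config: GAConfig,
    rng: np.random.Generator,
    generation: int,
) -> np.ndarray:
    """One generational replacement given precomputed internal (minimized)
    fitness values."""
    n_cross, n_mut = _child_counts(config)
    elite_idx = np.argsort(internal_fitness, kind="stable")[: config.elite_count]

    n_parents = 2 * n_cross + n_mut
    new = np.empty_like(population)
    new[: config.elite_count] = population[elite_idx]
    if n_parents > 0:
        expect = rank_scale(internal_fitness, n_parents, minimize=True)
        parents = select_stochastic_uniform(expect, n_parents, rng)
        parents = rng.permutation(parents)
        row = config.elite_count
        for i in range(n_cross):
            a, b = parents[2 * i], parents[2 * i + 1]
            new[row] = crossover_scattered(population[a], population[b], rng)
            row += 1
        for i in range(n_mut):
            p = parents[2 * n_cross + i]
            new[row] = mutate_gaussian(population[p], generation, config, rng)
            row += 1
    return new


def step_generation(
    population: np.ndarray,
    fitness_fn: Callable,
    config: GAConfig,
    rng: np.random.Generator,
    generation: int = 0,
) -> np.ndarray:
    """Advance one generation (maximizing ``fitness_fn``).

    The next generation is elite_count best copied unchanged, then
    round(crossover_fraction * (population_size - elite_count)) crossover
    children, then mutation children; parents are drawn by rank scaling
    followed by stochastic-uniform selection.
    """
    fitness = np.array([fitness_fn(ind) for ind in population], dtype=float)
    return _next_generation(population, -fitness, config, rng, generation)


def _evaluate(fitness_fn: Callable, population: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        return np.asarray(fitness_fn(population), dtype=float)
    return np.array([fitness_fn(ind) for ind in population], dtype=float)


def run_ga(
    fitness_fn: Callable,
    config: GAConfig,
    rng: np.random.Generator | int | None = None,
    vectorized: bool = False,
) -> GAResult:
    """Maximize ``fitness_fn`` over the configured box.

    Parameters
    ----------
    fitness_fn : callable
        Maps a gene vector (or, with ``vectorized=True``, an (n, k) array)
        to fitness; higher is better.
    config : GAConfig
    rng : numpy Generator, int seed, or None
        Falls back to ``config.seed``.
    vectorized : bool
        Evaluate the whole population in one call per generation.

    Returns
    -------
    GAResult
        Best individual/fitness, per-generation best and mean trace, and
        the termination reason (one of ``generations``,
        ``stall_generations``, ``stall_time``, ``time_limit``,
        ``fitness_limit``).

    Notes
    -----
    Termination checks, stall accounting and ranking all run on the negated
    objective; results are reported on the maximization scale.  With
    ``elite_count >= 1`` the per-generation best trace is non-decreasing.
    """
    if rng is None:
        rng = config.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    t0 = time.monotonic()
    nsub = config.n_subpopulations
    subpops = _split_population(initialize_population(config, rng), nsub)

    best_hist: list[float] = []
    mean_hist: list[float] = []
    best_internal = np.inf
    best_genes = subpops[0][0].copy()
    last_improve_gen = 0
    last_improve_time = t0
    reason = "generations"
    gen = 0

    for gen in range(config.generations):
        fits = [-_evaluate(fitness_fn, sp, vectorized) for sp in subpops]
        all_f = np.concatenate(fits)
        gen_best = all_f.min()
        if gen_best < best_internal:
            if best_internal - gen_best > config.function_tolerance:
                last_improve_gen = gen
                last_improve_time = time.monotonic()
            best_genes = np.vstack(subpops)[np.argmin(all_f)].copy()
            best_internal = gen_best
        best_hist.append(-best_internal)
        mean_hist.append(float(-all_f.mean()))

        now = time.monotonic()
        if -best_internal >= config.fitness_limit:
            reason = "fitness_limit"
            break
        if gen - last_improve_gen >= config.stall_generations:
            reason = "stall_generations"
            break
        if now - last_improve_time > config.stall_time_seconds:
            reason = "stall_time"
            break
        if now - t0 > config.time_limit_seconds:
            reason = "time_limit"
            break
        if gen == config.generations - 1:
            reason = "generations"
            break

        sub_cfg = config if nsub == 1 else _subpop_config(config)
        subpops = [
            _next_generation(sp, f, sub_cfg, rng, gen) for sp, f in zip(subpops, fits)
        ]
        if nsub > 1 and config.migration_interval > 0 and (gen + 1) % config.migration_interval == 0:
            subpops = _migrate(subpops, fitness_fn, config, vectorized)

    history = pd.DataFrame(
        {"generation": np.arange(len(best_hist)), "best": best_hist, "mean": mean_hist}
    )
    return GAResult(
        best_genes=best_genes,
        best_fitness=float(-best_internal),
        generations_run=len(best_hist),
        history=history,
        termination_reason=reason,
    )


def _split_population(pop: np.ndarray, nsub: int) -> list[np.ndarray]:
    return [p.copy() for p in np.array_split(pop, nsub)]


def _subpop_config(config: GAConfig) -> GAConfig:
    import copy

    sub = copy.copy(config)
    sub.population_size = max(config.population_size // config.n_subpopulations, 2)
    sub.elite_count = min(config.elite_count, sub.population_size - 1)
    return sub


def _migrate(
    subpops: list[np.ndarray], fitness_fn: Callable, config: GAConfig, vectorized: bool
) -> list[np.ndarray]:
    """Ring migration: the best fraction of subpopulation i replaces the
    worst of subpopulation i+1 (forward), and of i-1 as well when
    direction is 'both'."""
    nsub = len(subpops)
    moves = [(i, (i + 1) % nsub) for i in range(nsub)]
    if config.migration_direction == "both":
        moves += [(i, (i - 1) % nsub) for i in range(nsub)]
    fits = [-_evaluate(fitness_fn, sp, vectorized) for sp in subpops]
    out = [sp.copy() for sp in subpops]
    for src, dst in moves:
        n = max(int(round(config.migration_fraction * len(subpops[src]))), 1)
        best = np.argsort(fits[src], kind="stable")[:n]
        worst = np.argsort(fits[dst], kind="stable")[::-1][:n]
        out[dst][worst] = subpops[src][best]
    return out
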