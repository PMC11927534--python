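"""Adaptive multi-strategy differential evolution for hyperparameter search.

A standard DE loop (mutation, binomial crossover, greedy one-to-one
selection) over genomes in the unit hypercube, with two additions:

1. **Adaptive F and CR.** Per generation, the mutation factor F and
   crossover rate CR react to a convergence indicator c_t (windowed
   relative improvement of the best fitness) via a three-branch rule::

       F  = 0.2 + 0.5 r   if c_t <= 0.05      CR = 0.95
       F  = 0.3 + 0.5 r   if 0.05 < c_t <= 0.1  CR = 0.90
       F  = 0.5 + 0.5 r   if c_t > 0.1          CR = 0.70

   (r ~ U[0,1]), and/or inflate linearly as population diversity collapses::

       F  = F_base  + dF  * (1 - D_current / D_max)
       CR = CR_base + dCR * (1 - D_current / D_max)

   where D_current is the mean pairwise Euclidean distance of the genomes
   and D_max its value in the initial population.

2. **Stage-scheduled mutation.** The run is split into thirds: rand/1
   (exploration), then current-to-best/1 (balance), then best/1 and best/2
   alternating by generation parity (exploitation).

Mixed hyperparameter spaces (continuous, integer, categorical; linear or
log scale) are encoded to/from the unit hypercube by :class:`ParamSpace`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STRATEGIES = ("rand1", "best1", "current_to_best1", "best2")
_DISTINCT_NEEDED = {"rand1": 3, "best1": 2, "current_to_best1": 2, "best2": 4}


@dataclass
class Param:
    """One searchable hyperparameter."""

    name: str
    kind: str  # continuous | integer | categorical
    bounds: tuple[float, float] | None = None
    choices: Sequence | None = None
    scale: str = "linear"  # linear | log

    def __post_init__(self) -> None:
        if self.kind in ("continuous", "integer"):
            if self.bounds is None or not all(map(math.isfinite, self.bounds)):
                raise ValueError(f"{self.name}: finite bounds required")
            if self.scale == "log" and self.bounds[0] <= 0:
                raise ValueError(f"{self.name}: log scale needs positive bounds")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: choices must be non-empty")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind}")

    def decode(self, g: float):
        g = min(max(float(g), 0.0), 1.0)
        if self.kind == "categorical":
            k = len(self.choices)
            return self.choices[min(int(g * k), k - 1)]
        lo, hi = self.bounds
        if self.scale == "log":
            val = 10.0 ** (math.log10(lo) + g * (math.log10(hi) - math.log10(lo)))
        else:
            val = lo + g * (hi - lo)
        if self.kind == "integer":
            return int(round(val))
        return val


class ParamSpace:
    """Ordered collection of parameters, mapping genomes to assignments."""

    def __init__(self, params: Sequence[Param]):
        self.params = list(params)
        if len({p.name for p in self.params}) != len(self.params):
            raise ValueError("parameter names must be unique")

    def __len__(self) -> int:
        return len(self.params)

    def decode(self, genome: np.ndarray) -> dict:
        genome = np.asarray(genome, dtype=float)
        if genome.size != len(self.params):
            raise ValueError("genome dimension does not match the space")
        return {p.name: p.decode(g) for p, g in zip(self.params, genome)}


@dataclass
class HDEConfig:
    """Optimizer settings; NP=20, G_max=50 is the reference configuration."""

    np_pop: int = 20
    g_max: int = 50
    f_base: float = 0.5
    cr_base: float = 0.9
    d_f: float = 0.3
    d_cr: float = 0.05
    adapt_mode: str = "both"  # convergence | diversity | both
    window: int = 5           # generations for the convergence indicator
    # diversity restoration: when mean pairwise distance falls below
    # diversity_floor * D_max, the worst restart_frac of the population is
    # re-seeded uniformly (anti-premature-convergence); 0 disables it
    diversity_floor: float = 0.25
    restart_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.np_pop < 5:
            raise ValueError("population size must be at least 5")
        if self.g_max < 1:
            raise ValueError("g_max must be positive")
        if self.adapt_mode not in ("convergence", "diversity", "both"):
            raise ValueError("adapt_mode must be convergence, diversity or both")


@dataclass
class HDEState:
    """Per-run bookkeeping: population, adaptation trace, best solution."""

    population: np.ndarray
    fitness: np.ndarray
    x_best: np.ndarray
    f_best: float
    t: int = 0
    d_max: float = 0.0
    trace: list[float] = field(default_factory=list)
    f_trace: list[float] = field(default_factory=list)
    cr_trace: list[float] = field(default_factory=list)
    strategy_trace: list[str] = field(default_factory=list)
    c_trace: list[float] = field(default_factory=list)
    d_trace: list[float] = field(default_factory=list)


def schedule_strategy(t: int, g_max: int) -> str:
    """Stage schedule: thirds of the run, best1/best2 alternating at the end."""
    if not 1 <= t <= g_max:
        raise ValueError("generation index out of range")
    if t <= g_max / 3:
        return "rand1"
    if t <= 2 * g_max / 3:
        return "current_to_best1"
    return "best1" if t % 2 == 1 else "best2"


def adapt_convergence(c_t: float, rng: np.random.Generator) -> tuple[float, float]:
    """Three-branch adaptive rule for (F, CR) given the convergence indicator."""
    if c_t < 0:
        c_t = 0.0
    r = float(rng.uniform())
    if c_t <= 0.05:
        return 0.2 + 0.5 * r, 0.95
    if c_t <= 0.1:
        return 0.3 + 0.5 * r, 0.9
    return 0.5 + 0.5 * r, 0.7


def adapt_diversity(
    f_base: float, cr_base: float, d_f: float, d_cr: float,
    d_current: float, d_max: float,
) -> tuple[float, float]:
    """Inflate F and CR linearly as population diversity collapses."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    shrink = 1.0 - d_current / d_max
    f = f_base + d_f * shrink
    cr = cr_base + d_cr * shrink
    return _clamp_f(f), _clamp_cr(cr)


def _clamp_f(f: float) -> float:
    return float(min(max(f, 1e-6), 1.2))


def _clamp_cr(cr: float) -> float:
    return float(min(max(cr, 1e-6), 1.0))


def _distinct_indices(
    n: int, exclude: tuple[int, ...], k: int, rng: np.random.Generator
) -> list[int]:
    pool = [j for j in range(n) if j not in exclude]
    if len(pool) < k:
        raise ValueError("population too small for the mutation strategy")
    return list(rng.choice(pool, size=k, replace=False))


def mutate(
    population: np.ndarray,
    fitness: np.ndarray,
    i: int,
    strategy: str,
    f: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Produce the donor vector for individual ``i``; components clipped to [0,1]."""
    n = population.shape[0]
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy}")
    if n - 1 < _DISTINCT_NEEDED[strategy]:
        raise ValueError(f"population too small for {strategy}")
    best = population[int(np.argmax(fitness))]
    xi = population[i]
    if strategy == "rand1":
        r1, r2, r3 = _distinct_indices(n, (i,), 3, rng)
        v = population[r1] + f * (population[r2] - population[r3])
    elif strategy == "best1":
        r1, r2 = _distinct_indices(n, (i,), 2, rng)
        v = best + f * (population[r1] - population[r2])
    elif strategy == "current_to_best1":
        r1, r2 = _distinct_indices(n, (i,), 2, rng)
        v = xi + f * (best - xi) + f * (population[r1] - population[r2])
    else:  # best2
        r1, r2, r3, r4 = _distinct_indices(n, (i,), 4, rng)
        v = best + f * (population[r1] - population[r2]) + f * (
            population[r3] - population[r4]
        )
    return np.clip(v, 0.0, 1.0)


def crossover(
    parent: np.ndarray, donor: np.ndarray, cr: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover; j_rand guarantees at least one donor component."""
    parent = np.asarray(parent, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if parent.shape != donor.shape:
        raise ValueError("parent/donor dimension mismatch")
    dim = parent.size
    mask = rng.uniform(size=dim) < cr
    mask[rng.integers(dim)] = True
    return np.where(mask, donor, parent)


def _mean_pairwise_distance(population: np.ndarray) -> float:
    n = population.shape[0]
    if n < 2:
        return 0.0
    diffs = population[:, None, :] - population[None, :, :]
    dists = np.sqrt((diffs**2).sum(axis=-1))
    return float(dists[np.triu_indices(n, k=1)].mean())


def optimize(
    objective: Callable[[np.ndarray], float],
    space: ParamSpace,
    cfg: HDEConfig,
) -> tuple[dict, HDEState]:
    """Maximize ``objective(genome)`` over the unit hypercube.

    The objective is evaluated on raw genomes (decode inside it via
    ``space.decode`` if it consumes hyperparameters); a raising objective
    scores that trial at -inf. Returns the decoded best assignment and the
    full optimizer state/trace.
    """
    rng = np.random.default_rng(cfg.seed)
    dim = len(space)
    pop = rng.uniform(size=(cfg.np_pop, dim))

    def safe_eval(g: np.ndarray) -> float:
        try:
            return float(objective(g))
        except Exception:  # noqa: BLE001 - a failing genome is a bad trial
            logger.warning("objective failed on a genome; scored -inf", exc_info=True)
            return -math.inf

    fitness = np.array([safe_eval(g) for g in pop])
    best_idx = int(np.argmax(fitness))
    state = HDEState(
        population=pop,
        fitness=fitness,
        x_best=pop[best_idx].copy(),
        f_best=float(fitness[best_idx]),
        d_max=max(_mean_pairwise_distance(pop), 1e-12),
    )
    state.trace.append(state.f_best)

    f_t, cr_t = cfg.f_base, cfg.cr_base
    for t in range(1, cfg.g_max + 1):
        state.t = t
        d_current = _mean_pairwise_distance(pop)
        if (
            cfg.diversity_floor > 0
            and d_current < cfg.diversity_floor * state.d_max
        ):
            # diversity restoration: re-seed the worst individuals
            n_restart = max(1, int(round(cfg.restart_frac * cfg.np_pop)))
            worst = np.argsort(fitness)[:n_restart]
            pop[worst] = rng.uniform(size=(worst.size, dim))
            fitness[worst] = [safe_eval(g) for g in pop[worst]]
            best_idx = int(np.argmax(fitness))
            if fitness[best_idx] > state.f_best:
                state.f_best = float(fitness[best_idx])
                state.x_best = pop[best_idx].copy()
            d_current = _mean_pairwise_distance(pop)
        # convergence indicator: relative best-fitness improvement over a window
        w = min(cfg.window, len(state.trace) - 1)
        if w > 0:
            prev = state.trace[-1 - w]
            if math.isfinite(prev) and math.isfinite(state.f_best):
                c_t = abs(state.f_best - prev) / max(abs(prev), 1e-12)
            else:
                c_t = 1.0
        else:
            c_t = 1.0

        if cfg.adapt_mode == "convergence":
            f_t, cr_t = adapt_convergence(c_t, rng)
            f_t, cr_t = _clamp_f(f_t), _clamp_cr(cr_t)
        elif cfg.adapt_mode == "diversity":
            f_t, cr_t = adapt_diversity(
                cfg.f_base, cfg.cr_base, cfg.d_f, cfg.d_cr, d_current, state.d_max
            )
        else:  # both: draw from the convergence rule, then shift by diversity
            f_t, cr_t = adapt_convergence(c_t, rng)
            shrink = 1.0 - d_current / state.d_max
            f_t = _clamp_f(f_t + cfg.d_f * shrink)
            cr_t = _clamp_cr(cr_t + cfg.d_cr * shrink)

        strategy = schedule_strategy(t, cfg.g_max)
        new_pop = pop.copy()
        new_fit = fitness.copy()
        for i in range(cfg.np_pop):
            donor = mutate(pop, fitness, i, strategy, f_t, rng)
            trial = crossover(pop[i], donor, cr_t, rng)
            ft = safe_eval(trial)
            if ft > fitness[i]:  # greedy one-to-one selection (strict: ties keep the parent)
                new_pop[i] = trial
                new_fit[i] = ft
        pop, fitness = new_pop, new_fit
        best_idx = int(np.argmax(fitness))
        if fitness[best_idx] > state.f_best:
            state.f_best = float(fitness[best_idx])
            state.x_best = pop[best_idx].copy()
        state.population = pop
        state.fitness = fitness
        state.trace.append(state.f_best)
        state.f_trace.append(f_t)
        state.cr_trace.append(cr_t)
        state.strategy_trace.append(strategy)
        state.c_trace.append(c_t)
        state.d_trace.append(d_current)

    return space.decode(state.x_best), state
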