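"""Real-coded evolutionary algorithm for rate-law parameter estimation.

The genotype is a real-valued vector, each position confined to a
per-parameter search interval.  One generation applies, in order:
linear rank-based fitness assignment, roulette-wheel selection over the
rank scores, BLX-alpha blend crossover, real-number creep mutation
(additive Gaussian with a geometrically annealed scale), and clipping
to the bounds.  The best individual is cloned unchanged into the next
generation, so the best-so-far objective is non-increasing.

In addition to the blended offspring, a small share of each generation
consists of creep-mutated clones of a few *climber* lineages: the
current best individual plus up to two rank-selected individuals kept
mutually distant.  Each climber's creep scale self-adapts by the
classic one-fifth success rule, and a stagnated climber lineage is
restarted from a fresh roulette pick.  This is the package's
realization of the cloning/creep operator pair; it gives the algorithm
the local refinement needed to recover rate-law parameters to several
decimal places from a limited generation budget, while the blended
herd keeps exploring.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

#: Fitness sentinel assigned to candidates whose simulation failed.
WORST_FITNESS = 1e30


@dataclass(frozen=True)
class EAConfig:
    """Evolutionary-algorithm settings.

    Defaults are the full-scale study configuration: population 500,
    300 generations, crossover rate 0.6, mutation rate 0.1, five
    independent repeats per optimization.  The remaining knobs are the
    package's own operator choices: ``blx_alpha`` (spread of the blend
    crossover), ``creep_scale``/``creep_decay`` (herd mutation std as
    a fraction of each bound width, annealed geometrically),
    ``selection_pressure`` (linear-ranking slope), ``seed_fraction``
    (share of a seeded initial population built from supplied
    individuals), and the climber-lineage block sizes.
    """

    population: int = 500
    generations: int = 300
    crossover_rate: float = 0.6
    blx_alpha: float = 0.5
    mutation_rate: float = 0.1
    creep_scale: float = 0.05
    creep_decay: float = 1e-3
    selection_pressure: float = 1.8
    elites: int = 1
    repeats: int = 5
    seed_fraction: float = 0.1
    seed: int | None = None
    #: number of hill-climbing lineages maintained by the creep operator
    n_climbers: int = 3
    #: creep-mutated clones produced per climber per generation
    climber_children: int = 8
    #: generations without improvement before a climber restarts
    climber_stall: int = 12

    def scaled(self, **kw) -> "EAConfig":
        return replace(self, **kw)


@dataclass
class EAResult:
    """Outcome of one evolutionary run."""

    best_x: np.ndarray
    best_f: float
    history: np.ndarray  # best-so-far objective per generation
    mean_history: np.ndarray | None = None  # population mean (finite only)
    seed: int | None = None


def _rank_scores(fitness: np.ndarray, pressure: float) -> np.ndarray:
    """Linear ranking: worst scores 2-sp, best scores sp; roulette weights."""
    p = len(fitness)
    order = np.argsort(-fitness)  # ascending quality: worst first
    pos = np.empty(p)
    pos[order] = np.arange(p)
    if p == 1:
        return np.ones(1)
    return (2.0 - pressure) + 2.0 * (pressure - 1.0) * pos / (p - 1)


class _Climber:
    """One elitist hill-climbing lineage with 1/5-rule step adaptation."""

    __slots__ = ("x", "f", "sigma", "stall")

    def __init__(self, x: np.ndarray, f: float, sigma: float = 0.05):
        self.x = x.copy()
        self.f = float(f)
        self.sigma = sigma
        self.stall = 0


def ea_optimize(
    objective: Callable[[np.ndarray], np.ndarray | float],
    lower: np.ndarray,
    upper: np.ndarray,
    config: EAConfig | None = None,
    rng: np.random.Generator | int | None = None,
    initial: np.ndarray | None = None,
    vectorized: bool = False,
) -> EAResult:
    """Minimize ``objective`` over the box ``[lower, upper]``.

    ``objective`` maps a parameter vector to a non-negative value (or,
    with ``vectorized=True``, a (P, d) matrix to a length-P vector);
    non-finite values are replaced by a worst-fitness sentinel.
    ``initial`` optionally injects seed individuals (plus mutated
    copies) into the first population.
    """
    config = config or EAConfig()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or np.any(upper <= lower):
        raise ValueError("bounds must satisfy lower < upper elementwise")
    d = lower.shape[0]
    width = upper - lower
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    pop_n = config.population
    pop = lower + width * rng.random((pop_n, d))

    if initial is not None:
        initial = np.atleast_2d(np.asarray(initial, dtype=float))
        n_seeded = min(pop_n, max(len(initial),
                                  int(round(config.seed_fraction * pop_n))))
        block = np.empty((n_seeded, d))
        for i in range(n_seeded):
            base = initial[i % len(initial)]
            if i < len(initial):
                block[i] = base
            else:  # mutated copy of a seed individual
                block[i] = base + rng.normal(
                    0.0, config.creep_scale * width, d)
        pop[:n_seeded] = np.clip(block, lower, upper)

    def evaluate(p: np.ndarray) -> np.ndarray:
        if vectorized:
            f = np.asarray(objective(p), dtype=float)
        else:
            f = np.array([float(objective(ind)) for ind in p])
        f[~np.isfinite(f)] = WORST_FITNESS
        return f

    fitness = evaluate(pop)
    if np.all(fitness >= WORST_FITNESS):
        raise RuntimeError(
            "objective is non-finite on every initial individual"
        )

    best_idx = int(np.argmin(fitness))
    best_x = pop[best_idx].copy()
    best_f = float(fitness[best_idx])
    history = np.empty(config.generations + 1)
    history[0] = best_f
    mean_history = np.empty(config.generations + 1)

    def finite_mean(f: np.ndarray) -> float:
        ok = f < WORST_FITNESS
        return float(f[ok].mean()) if np.any(ok) else WORST_FITNESS

    mean_history[0] = finite_mean(fitness)

    # climber block sizing; shrink for small populations
    per_climb = config.climber_children
    n_climb = config.n_climbers
    while n_climb > 0 and n_climb * per_climb > (pop_n - config.elites) // 2:
        n_climb -= 1
    climbers: list[_Climber] = []

    def spawn_climber(prob: np.ndarray) -> _Climber:
        pick = int(rng.choice(pop_n, p=prob))
        return _Climber(pop[pick], fitness[pick])

    for gen in range(config.generations):
        scores = _rank_scores(fitness, config.selection_pressure)
        prob = scores / scores.sum()

        # maintain the climber lineages: best individual plus
        # rank-selected, mutually distant starts
        if n_climb > 0:
            if not climbers:
                climbers.append(_Climber(best_x, best_f))
                while len(climbers) < n_climb:
                    climbers.append(spawn_climber(prob))
            if climbers[0].f > best_f:
                climbers[0] = _Climber(best_x, best_f,
                                       sigma=climbers[0].sigma)
            for ci in range(1, len(climbers)):
                c = climbers[ci]
                if c.stall >= config.climber_stall or c.sigma <= 1e-9:
                    climbers[ci] = spawn_climber(prob)

        n_ec = len(climbers) * per_climb
        n_children = pop_n - config.elites - n_ec
        parents_a = pop[rng.choice(pop_n, n_children, p=prob)]
        parents_b = pop[rng.choice(pop_n, n_children, p=prob)]

        # BLX-alpha: child uniform in the parent interval widened by
        # alpha on each side; applied per mating at the crossover rate.
        cross = rng.random(n_children) < config.crossover_rate
        lo = np.minimum(parents_a, parents_b)
        hi = np.maximum(parents_a, parents_b)
        span = hi - lo
        blx_lo = lo - config.blx_alpha * span
        blx_hi = hi + config.blx_alpha * span
        blended = blx_lo + (blx_hi - blx_lo) * rng.random((n_children, d))
        children = np.where(cross[:, None], blended, parents_a)

        # herd creep mutation: per-position additive Gaussian with a
        # geometrically annealed scale
        decay = config.creep_decay ** (gen / max(config.generations - 1, 1))
        mutate = rng.random((n_children, d)) < config.mutation_rate
        children = children + mutate * rng.normal(
            0.0, config.creep_scale * decay * width, (n_children, d))
        children = np.clip(children, lower, upper)

        # climber creep blocks: adaptive-scale clones of each lineage
        blocks = [np.clip(c.x + rng.normal(0.0, c.sigma * width,
                                           (per_climb, d)),
                          lower, upper)
                  for c in climbers]

        order = np.argsort(fitness)
        elite_rows = np.vstack(
            [best_x] + [pop[i] for i in order[: config.elites - 1]]
        )
        pop = np.vstack([elite_rows] + blocks + [children])
        fitness = evaluate(pop)

        # one-fifth success rule per climber
        off = config.elites
        for c in climbers:
            block_f = fitness[off:off + per_climb]
            improved = block_f < c.f
            if np.any(improved):
                j = off + int(np.argmin(block_f))
                c.x = pop[j].copy()
                c.f = float(fitness[j])
                c.stall = 0
            else:
                c.stall += 1
            c.sigma *= 1.3 if np.sum(improved) > per_climb / 5 else 0.85
            c.sigma = float(np.clip(c.sigma, 1e-10, 0.2))
            off += per_climb

        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_f:
            best_f = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
        history[gen + 1] = best_f
        mean_history[gen + 1] = finite_mean(fitness)

    return EAResult(best_x=best_x, best_f=best_f, history=history,
                    mean_history=mean_history, seed=config.seed)
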