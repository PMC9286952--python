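"""Improved Archimedes optimization algorithm (IAOA).

Two modifications are layered on the baseline optimizer in :mod:`~iaoadbn.aoa`:

1. *Sine-chaos + opposition-based initialization.* Candidate positions are
   generated from the infinite-collapse sine map ``x_{t+1} = sin(2/x_t)``
   (one chaotic stream per dimension), which covers the search box more
   evenly than uniform draws; the population is then mirrored through the
   per-dimension dynamic boundary (opposition-based learning) and the
   fitter half of the union seeds the run.

2. *Gaussian elite mutation with superior selection.* After every iteration
   the incumbent best is perturbed multiplicatively, component-wise, by
   ``x * (1 + N(0, sigma))`` and the mutant replaces the incumbent only when
   a coin with probability ``p`` allows it *and* it strictly improves the
   objective, so the best-so-far trace stays monotone while the incumbent
   can escape local basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import aoa
from .aoa import AoaConfig, OptimizerResult, _batch_eval

__all__ = [
    "IaoaConfig",
    "sine_chaos_sequence",
    "chaos_initialize",
    "opposition_population",
    "merge_select",
    "gaussian_elite_mutation",
    "optimize",
]


@dataclass
class IaoaConfig(AoaConfig):
    """AOA parameters plus the mutation probability ``p``, the Gaussian
    spread ``sigma`` and the chaotic-stream burn-in length."""

    mutation_probability: float = 0.5
    gaussian_sigma: float = 1.0
    chaos_burn_in: int = 100

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must lie in [0, 1]")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.chaos_burn_in < 0:
            raise ValueError("chaos_burn_in must be non-negative")


def sine_chaos_sequence(
    x0: float, length: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Iterate the sine chaotic map ``x_{t+1} = sin(2 / x_t)``.

    Returns the ``length`` iterates following ``x0``; every value lies in
    [-1, 1]. An iterate that lands exactly on 0 (where the map is undefined)
    is replaced by a fresh uniform draw from ``rng``.
    """
    x0 = float(x0)
    if x0 == 0.0 or abs(x0) > 1.0:
        raise ValueError("x0 must lie in [-1, 1] and differ from 0")
    out = np.empty(length)
    x = x0
    for i in range(length):
        x = float(np.sin(2.0 / x))
        if x == 0.0:
            if rng is None:
                raise ValueError("chaotic iterate hit exactly 0 and no rng was given to reseed")
            while x == 0.0:
                x = float(rng.uniform(-1.0, 1.0))
        out[i] = x
    return out


def chaos_initialize(config: IaoaConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Generate an ``(n, d)`` position matrix from per-dimension chaotic streams.

    Each dimension runs its own sine-chaos stream (seed value uniform in
    [-1, 1] excluding 0, then ``chaos_burn_in`` discarded iterates) and the
    chaotic values are mapped affinely from [-1, 1] onto that dimension's
    bounds.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, d = config.population_size, config.dimension
    lo, hi = config.lower, config.upper
    X = np.empty((n, d))
    for j in range(d):
        x0 = 0.0
        while x0 == 0.0:
            x0 = float(rng.uniform(-1.0, 1.0))
        stream = sine_chaos_sequence(x0, config.chaos_burn_in + n, rng)[config.chaos_burn_in:]
        X[:, j] = lo[j] + (stream + 1.0) / 2.0 * (hi[j] - lo[j])
    return X


def opposition_population(X: np.ndarray) -> np.ndarray:
    """Mirror every candidate through the population's dynamic boundary.

    X*_ij = min_j + max_j - X_ij, with min_j/max_j the per-dimension extremes
    of the current population (not the static search bounds).
    """
    X = np.asarray(X, dtype=float)
    return X.min(axis=0) + X.max(axis=0) - X


def merge_select(
    X: np.ndarray,
    X_star: np.ndarray,
    objective,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Keep the ``n`` fittest rows of the union of ``X`` and ``X_star``.

    Ties are broken by position in the concatenation (original population
    before its opposition), making the selection deterministic.
    """
    X = np.asarray(X, dtype=float)
    union = np.vstack([X, X_star])
    fitness = _batch_eval(objective, union, rng)
    order = np.argsort(fitness, kind="stable")[: X.shape[0]]
    return union[order]


def gaussian_elite_mutation(
    best_position: np.ndarray,
    best_fitness: float,
    objective,
    p: float,
    sigma: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, int]:
    """Perturb the incumbent multiplicatively and keep it only if superior.

    The candidate is ``best * (1 + g)`` with one independent ``N(0, sigma)``
    draw per dimension; it replaces the incumbent only when a uniform draw
    falls below ``p`` *and* the candidate objective is strictly smaller.
    Returns ``(position, fitness, n_evaluations_used)``. Note the
    multiplicative form cannot move a coordinate that is exactly 0.
    """
    best_position = np.asarray(best_position, dtype=float)
    g = rng.normal(0.0, sigma, size=best_position.shape)
    gate = rng.random()
    if gate >= p:
        return best_position, float(best_fitness), 0
    candidate = best_position * (1.0 + g)
    f_cand = float(_batch_eval(objective, candidate[None, :], rng)[0])
    if f_cand < best_fitness:
        return candidate, f_cand, 1
    return best_position, float(best_fitness), 1


def optimize(objective, config: IaoaConfig, rng: np.random.Generator | None = None) -> OptimizerResult:
    """Run the improved optimizer.

    Chaos + opposition initialization feeds the baseline AOA loop, and the
    Gaussian elite mutation runs after every iteration. The best-so-far
    trace is monotone non-increasing and the whole run is reproducible from
    ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    X = chaos_initialize(config, rng)
    X = np.clip(X, config.lower, config.upper)
    X_star = opposition_population(X)
    init = merge_select(X, X_star, objective, rng)

    def _elite(pop, hook_rng):
        pos, fit, used = gaussian_elite_mutation(
            pop.best_position,
            pop.best_fitness,
            objective,
            config.mutation_probability,
            config.gaussian_sigma,
            hook_rng,
        )
        if fit < pop.best_fitness:
            pop.best_position = pos
            pop.best_fitness = fit
        return used

    return aoa.optimize(objective, config, initial_positions=init, elite_hook=_elite, rng=rng)
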