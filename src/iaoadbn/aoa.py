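"""Archimedes optimization algorithm (AOA).

A population metaheuristic in which each candidate solution is a "material"
immersed in a fluid, carrying a density ``den``, a volume ``vol`` and an
acceleration ``acc`` in addition to its position. Densities and volumes relax
toward the incumbent best each iteration; accelerations are set either from a
random material (exploration, collision) or from the best material
(exploitation, equilibrium), the switch being governed by a transfer factor

    TF(t) = exp((t - t_max) / t_max),

which rises toward 1 so that late iterations exploit. Step sizes shrink under
the density factor

    d(t) = exp((t_max - t) / t_max) - t / t_max.

All objectives are minimized inside box bounds; positions are clipped
component-wise after every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .benchfuncs import BenchmarkFunction, evaluate_batch

__all__ = [
    "AoaConfig",
    "AoaPopulation",
    "OptimizerResult",
    "transfer_factor",
    "density_factor",
    "initialize",
    "update_density_volume",
    "update_acceleration",
    "normalize_acceleration",
    "update_positions",
    "optimize",
]

_EPS = 1e-12  # floor for den*vol products in the acceleration denominator


@dataclass
class AoaConfig:
    """Run parameters for the optimizer.

    ``C1``..``C4`` are the step-size constants (defaults 2, 6, 1, 2); ``u``
    and ``l`` set the range of the acceleration normalization (outputs fall
    in ``[l, u + l]``). ``exploit_form`` selects the exploitation attractor:
    ``"canonical"`` uses the displacement ``T*x_best - x_i``; ``"as_printed"``
    uses ``T*(x_best - x_i)``.
    """

    bounds: Sequence | np.ndarray  # (d, 2) per-dimension (lower, upper)
    population_size: int = 30
    max_iterations: int = 500
    C1: float = 2.0
    C2: float = 6.0
    C3: float = 1.0
    C4: float = 2.0
    u: float = 0.9
    l: float = 0.1
    seed: int = 0
    exploit_form: str = "canonical"

    def __post_init__(self):
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2 or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must be a (d, 2) array with lower < upper")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be non-negative")
        if not (self.u > self.l > 0):
            raise ValueError("normalization range requires u > l > 0")
        if self.exploit_form not in ("canonical", "as_printed"):
            raise ValueError("exploit_form must be 'canonical' or 'as_printed'")

    @property
    def dimension(self) -> int:
        return self.bounds.shape[0]

    @property
    def lower(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return self.bounds[:, 1]


@dataclass
class AoaPopulation:
    """State of the material population plus the incumbent best."""

    positions: np.ndarray       # (n, d)
    densities: np.ndarray       # (n,)
    volumes: np.ndarray         # (n,)
    accelerations: np.ndarray   # (n, d)
    fitness: np.ndarray         # (n,)
    best_position: np.ndarray
    best_density: float
    best_volume: float
    best_acceleration: np.ndarray
    best_fitness: float
    acc_normalized: np.ndarray | None = field(default=None, repr=False)

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    def _maybe_update_best(self) -> None:
        i = int(np.argmin(self.fitness))
        if self.fitness[i] < self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()
            self.best_density = float(self.densities[i])
            self.best_volume = float(self.volumes[i])
            # the incumbent keeps its *normalized* acceleration: the raw one
            # regrows by 1/(den*vol) at every incumbent change and diverges
            acc = self.acc_normalized if self.acc_normalized is not None else self.accelerations
            self.best_acceleration = acc[i].copy()


@dataclass
class OptimizerResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best-so-far fitness, entry 0 = after initialization
    n_evaluations: int


def _batch_eval(objective, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if isinstance(objective, BenchmarkFunction):
        return evaluate_batch(objective, X, rng)
    return np.asarray(objective(X), dtype=float)


def transfer_factor(t: int, t_max: int) -> float:
    """TF(t) = exp((t - t_max)/t_max); strictly increasing, TF(t_max) = 1."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return float(np.exp((t - t_max) / t_max))


def density_factor(t: int, t_max: int) -> float:
    """d(t) = exp((t_max - t)/t_max) - t/t_max; strictly decreasing, d(t_max) = 0."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return float(np.exp((t_max - t) / t_max) - t / t_max)


def initialize(
    config: AoaConfig,
    objective,
    rng: np.random.Generator | None = None,
    positions: np.ndarray | None = None,
) -> AoaPopulation:
    """Draw the initial population and select the incumbent.

    Positions are uniform inside the bounds (or taken from ``positions``,
    the hook used by chaos-initialized variants); densities and volumes are
    uniform in (0, 1); accelerations are uniform on the bound scale.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, d = config.population_size, config.dimension
    lo, hi = config.lower, config.upper
    if positions is None:
        positions = lo + rng.random((n, d)) * (hi - lo)
    else:
        positions = np.clip(np.asarray(positions, dtype=float), lo, hi)
        if positions.shape != (n, d):
            raise ValueError(f"positions must have shape {(n, d)}")
    densities = rng.random(n)
    volumes = rng.random(n)
    accelerations = lo + rng.random((n, d)) * (hi - lo)
    fitness = _batch_eval(objective, positions, rng)
    if not np.all(np.isfinite(fitness)):
        bad = positions[int(np.flatnonzero(~np.isfinite(fitness))[0])]
        raise FloatingPointError(f"objective is non-finite at initial point {bad}")
    i = int(np.argmin(fitness))
    return AoaPopulation(
        positions=positions,
        densities=densities,
        volumes=volumes,
        accelerations=accelerations,
        fitness=fitness,
        best_position=positions[i].copy(),
        best_density=float(densities[i]),
        best_volume=float(volumes[i]),
        best_acceleration=accelerations[i].copy(),
        best_fitness=float(fitness[i]),
    )


def update_density_volume(pop: AoaPopulation, rng: np.random.Generator) -> AoaPopulation:
    """Relax each material's density and volume toward the incumbent's.

    den_i <- den_i + r1*(den_best - den_i), vol_i <- vol_i + r2*(vol_best -
    vol_i), with fresh uniform draws per material and per quantity.
    """
    n = pop.size
    pop.densities = pop.densities + rng.random(n) * (pop.best_density - pop.densities)
    pop.volumes = pop.volumes + rng.random(n) * (pop.best_volume - pop.volumes)
    return pop


def update_acceleration(pop: AoaPopulation, TF: float, rng: np.random.Generator) -> AoaPopulation:
    """Set accelerations from a random material (TF <= 0.5) or the best one.

    Exploration transfers momentum from a uniformly chosen random material
    ``mr``: acc_i <- (den_mr + vol_mr*acc_mr) / (den_i*vol_i). Exploitation
    replaces ``mr`` with the incumbent best. The denominator is floored at
    1e-12 to guard degenerate products.
    """
    n = pop.size
    denom = np.maximum(pop.densities * pop.volumes, _EPS)[:, None]
    if TF <= 0.5:
        mr = rng.integers(0, n, size=n)
        num = pop.densities[mr, None] + pop.volumes[mr, None] * pop.accelerations[mr]
    else:
        num = pop.best_density + pop.best_volume * pop.best_acceleration[None, :]
    # repeated amplification through small den*vol products can compound;
    # cap the magnitude (min-max normalization is unaffected by the scale)
    pop.accelerations = np.clip(num / denom, -1e100, 1e100)
    return pop


def normalize_acceleration(pop: AoaPopulation, u: float, l: float) -> AoaPopulation:
    """Min-max rescale accelerations into [l, u + l] (population-wide range).

    When every acceleration component is identical the range is degenerate
    and all normalized values are set to ``l``.
    """
    acc = pop.accelerations
    amin, amax = float(np.min(acc)), float(np.max(acc))
    # a numerically degenerate range would amplify 1-ulp noise into the full
    # [l, u+l] band; collapse it to l instead
    if amax - amin <= 1e-9 * max(abs(amax), abs(amin), 1e-300):
        pop.acc_normalized = np.full_like(acc, l)
    else:
        pop.acc_normalized = u * (acc - amin) / (amax - amin) + l
    return pop


def update_positions(
    pop: AoaPopulation,
    TF: float,
    d_factor: float,
    config: AoaConfig,
    rng: np.random.Generator,
    objective,
) -> AoaPopulation:
    """Move every material, clip to bounds, re-evaluate, update the incumbent.

    Exploration (TF <= 0.5) steps toward a random material's position;
    exploitation steps around the incumbent with a random direction flag
    F = +1 if (2*rand - C4) <= 0.5 else -1 and attractor scale T = C3*TF.
    The step draw is one scalar uniform per material, so exploitation
    samples whole-vector contractions anchored at the incumbent.
    """
    n, dim = pop.positions.shape
    acc_n = pop.acc_normalized
    if acc_n is None:
        raise RuntimeError("normalize_acceleration must run before update_positions")
    if TF <= 0.5:
        xr = pop.positions[rng.integers(0, n, size=n)]
        step = config.C1 * rng.random((n, 1)) * acc_n * d_factor * (xr - pop.positions)
        pop.positions = pop.positions + step
    else:
        p = 2.0 * rng.random(n) - config.C4
        F = np.where(p <= 0.5, 1.0, -1.0)[:, None]
        T = config.C3 * TF
        if config.exploit_form == "canonical":
            disp = T * pop.best_position[None, :] - pop.positions
        else:
            disp = T * (pop.best_position[None, :] - pop.positions)
        pop.positions = pop.best_position[None, :] + F * config.C2 * rng.random((n, 1)) * acc_n * d_factor * disp
    pop.positions = np.clip(pop.positions, config.lower, config.upper)
    pop.fitness = _batch_eval(objective, pop.positions, rng)
    pop._maybe_update_best()
    return pop


def optimize(
    objective,
    config: AoaConfig,
    initial_positions: np.ndarray | None = None,
    elite_hook: Callable | None = None,
    rng: np.random.Generator | None = None,
) -> OptimizerResult:
    """Run the full AOA loop and return the best solution found.

    ``objective`` is either a :class:`~iaoadbn.benchfuncs.BenchmarkFunction`
    or any callable mapping an ``(n, d)`` matrix to ``n`` objective values.
    ``initial_positions`` and ``elite_hook`` are the extension points used by
    the improved variant (chaos/opposition initialization and elite
    mutation); ``elite_hook(pop, rng)`` runs after each iteration and may
    only improve the incumbent.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize(config, objective, rng, positions=initial_positions)
    n_evals = pop.size
    trace = [pop.best_fitness]
    t_max = config.max_iterations
    for t in range(1, t_max + 1):
        TF = transfer_factor(t, t_max)
        d_factor = density_factor(t, t_max)
        update_density_volume(pop, rng)
        update_acceleration(pop, TF, rng)
        normalize_acceleration(pop, config.u, config.l)
        update_positions(pop, TF, d_factor, config, rng, objective)
        n_evals += pop.size
        if elite_hook is not None:
            n_evals += elite_hook(pop, rng)
        trace.append(pop.best_fitness)
    return OptimizerResult(
        best_position=pop.best_position.copy(),
        best_fitness=pop.best_fitness,
        trace=np.asarray(trace),
        n_evaluations=n_evals,
    )
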