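"""Registry of the 13 classical benchmark objectives used to compare optimizers.

The suite is the standard one used throughout the metaheuristics literature:
five unimodal functions (F1-F5), five high-dimensional multimodal functions
(F6-F10), and three fixed-dimension multimodal functions (F11-F13). All are
minimization problems with box bounds; every function except the noisy
Quartic (F5) is deterministic.

=====  =============  =================  ===========
id     name           bounds             optimum
=====  =============  =================  ===========
F1     Sphere         [-100, 100]^30     0
F2     Schwefel 2.22  [-10, 10]^30       0
F3     Schwefel 1.2   [-100, 100]^30     0
F4     Schwefel 2.21  [-100, 100]^30     0
F5     Quartic+noise  [-1.28, 1.28]^30   0 (noise-free)
F6     Rastrigin      [-5.12, 5.12]^30   0
F7     Ackley         [-32, 32]^30       0
F8     Griewank       [-600, 600]^30     0
F9     Penalized 1    [-50, 50]^30       0
F10    Penalized 2    [-50, 50]^30       0
F11    Kowalik        [-5, 5]^4          3.0749e-4
F12    Six-hump camel [-5, 5]^2          -1.0316285
F13    Branin         [-5,10]x[0,15]     0.3978874
=====  =============  =================  ===========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "BenchmarkFunction",
    "get_function",
    "list_functions",
    "evaluate_batch",
    "multistart_minimize",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named box-bounded minimization objective with a known optimum."""

    name: str
    canonical_name: str
    dimension: int
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    known_optimum: float
    _fn: Callable[[np.ndarray, np.random.Generator | None], np.ndarray] = field(repr=False)
    stochastic: bool = False

    def evaluate(self, x, rng: np.random.Generator | None = None) -> float:
        """Evaluate at a single point ``x`` of length ``dimension``.

        ``rng`` feeds the noise term of stochastic functions (F5) and is
        ignored by deterministic ones; with ``rng=None`` the noise is zero.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dimension,):
            raise ValueError(
                f"{self.name} expects a vector of length {self.dimension}, got shape {x.shape}"
            )
        return float(self._fn(x[None, :], rng)[0])

    def __call__(self, X, rng: np.random.Generator | None = None) -> np.ndarray:
        """Vectorized evaluation of an ``n x d`` matrix of points."""
        return evaluate_batch(self, X, rng)

    @property
    def bounds(self) -> np.ndarray:
        """``(d, 2)`` array of per-dimension (lower, upper) bounds."""
        return np.column_stack([self.lower_bound, self.upper_bound])

    def metadata(self) -> dict:
        return {
            "name": self.name,
            "canonical_name": self.canonical_name,
            "dimension": self.dimension,
            "lower_bound": self.lower_bound.tolist(),
            "upper_bound": self.upper_bound.tolist(),
            "optimum": self.known_optimum,
            "stochastic": self.stochastic,
        }


def evaluate_batch(fn: BenchmarkFunction, X, rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply ``fn`` to every row of ``X`` (``n x d``), returning ``n`` values."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or (X.shape[0] > 0 and X.shape[1] != fn.dimension):
        raise ValueError(
            f"expected an (n, {fn.dimension}) matrix for {fn.name}, got shape {X.shape}"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    return np.asarray(fn._fn(X, rng), dtype=float)


# --- definitions (all take an (n, d) matrix, return length-n vector) ---

def _sphere(X, rng):
    return np.sum(X**2, axis=1)


def _schwefel_222(X, rng):
    a = np.abs(X)
    return np.sum(a, axis=1) + np.prod(a, axis=1)


def _schwefel_12(X, rng):
    return np.sum(np.cumsum(X, axis=1) ** 2, axis=1)


def _schwefel_221(X, rng):
    return np.max(np.abs(X), axis=1)


def _quartic_noise(X, rng):
    i = np.arange(1, X.shape[1] + 1)
    base = np.sum(i * X**4, axis=1)
    if rng is not None:
        base = base + rng.random(X.shape[0])
    return base


def _rastrigin(X, rng):
    return 10.0 * X.shape[1] + np.sum(X**2 - 10.0 * np.cos(2 * np.pi * X), axis=1)


def _ackley(X, rng):
    d = X.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(X**2, axis=1) / d))
        - np.exp(np.sum(np.cos(2 * np.pi * X), axis=1) / d)
        + 20.0
        + np.e
    )


def _griewank(X, rng):
    i = np.sqrt(np.arange(1, X.shape[1] + 1))
    s = np.sum(X**2, axis=1) / 4000.0
    p = np.prod(np.cos(X / i), axis=1)
    # evaluated as s - p + 1 so that points within ~1e-9 of the origin
    # cancel to an exact 0.0 in double precision
    return s - p + 1.0


def _penalty(X, a, k, m):
    return np.sum(
        np.where(X > a, k * (X - a) ** m, np.where(X < -a, k * (-X - a) ** m, 0.0)),
        axis=1,
    )


def _penalized1(X, rng):
    d = X.shape[1]
    y = 1.0 + (X + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[:, 0]) ** 2
        + np.sum((y[:, :-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2), axis=1)
        + (y[:, -1] - 1.0) ** 2
    )
    return np.pi / d * term + _penalty(X, 10.0, 100.0, 4)


def _penalized2(X, rng):
    term = (
        np.sin(3 * np.pi * X[:, 0]) ** 2
        + np.sum((X[:, :-1] - 1.0) ** 2 * (1.0 + np.sin(3 * np.pi * X[:, 1:]) ** 2), axis=1)
        + (X[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2 * np.pi * X[:, -1]) ** 2)
    )
    return 0.1 * term + _penalty(X, 5.0, 100.0, 4)


# Kowalik: 4-parameter, 11-datum rational least-squares fit
_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
     0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1, 2, 4, 6, 8, 10, 12, 14, 16])


def _kowalik(X, rng):
    b = _KOWALIK_B
    num = X[:, [0]] * (b**2 + b * X[:, [1]])
    den = b**2 + b * X[:, [2]] + X[:, [3]]
    return np.sum((_KOWALIK_A - num / den) ** 2, axis=1)


def _six_hump(X, rng):
    x, y = X[:, 0], X[:, 1]
    return 4 * x**2 - 2.1 * x**4 + x**6 / 3.0 + x * y - 4 * y**2 + 4 * y**4


def _branin(X, rng):
    x, y = X[:, 0], X[:, 1]
    a, b, c = 1.0, 5.1 / (4 * np.pi**2), 5.0 / np.pi
    s, t = 10.0, 1.0 / (8 * np.pi)
    return a * (y - b * x**2 + c * x - 6.0) ** 2 + s * (1 - t) * np.cos(x) + s


def _make(name, canonical, dim, lo, hi, optimum, fn, stochastic=False):
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (dim,)).copy()
    return BenchmarkFunction(name, canonical, dim, lo, hi, optimum, fn, stochastic)


_REGISTRY: dict[str, BenchmarkFunction] = {}
_ALIASES: dict[str, str] = {}

for _f in [
    _make("F1", "sphere", 30, -100, 100, 0.0, _sphere),
    _make("F2", "schwefel_2_22", 30, -10, 10, 0.0, _schwefel_222),
    _make("F3", "schwefel_1_2", 30, -100, 100, 0.0, _schwefel_12),
    _make("F4", "schwefel_2_21", 30, -100, 100, 0.0, _schwefel_221),
    _make("F5", "quartic_noise", 30, -1.28, 1.28, 0.0, _quartic_noise, stochastic=True),
    _make("F6", "rastrigin", 30, -5.12, 5.12, 0.0, _rastrigin),
    _make("F7", "ackley", 30, -32, 32, 0.0, _ackley),
    _make("F8", "griewank", 30, -600, 600, 0.0, _griewank),
    _make("F9", "penalized_1", 30, -50, 50, 0.0, _penalized1),
    _make("F10", "penalized_2", 30, -50, 50, 0.0, _penalized2),
    _make("F11", "kowalik", 4, -5, 5, 3.0749e-4, _kowalik),
    _make("F12", "six_hump_camel", 2, -5, 5, -1.0316285, _six_hump),
    _make("F13", "branin", 2, [-5.0, 0.0], [10.0, 15.0], 0.3978874, _branin),
]:
    _REGISTRY[_f.name] = _f
    _ALIASES[_f.name.lower()] = _f.name
    _ALIASES[_f.canonical_name] = _f.name


def list_functions() -> list[str]:
    """Names of all registered functions, in suite order."""
    return list(_REGISTRY)


def get_function(name: str) -> BenchmarkFunction:
    """Look up a benchmark function by id (``"F1"``..``"F13"``) or canonical alias."""
    key = _ALIASES.get(str(name).strip().lower().replace("-", "_"))
    if key is None:
        valid = ", ".join(list(_REGISTRY) + sorted(set(_ALIASES) - {k.lower() for k in _REGISTRY}))
        raise KeyError(f"unknown benchmark function {name!r}; valid identifiers: {valid}")
    return _REGISTRY[key]


def multistart_minimize(
    fn: BenchmarkFunction,
    n_starts: int = 100,
    seed: int = 0,
    method: str = "Nelder-Mead",
) -> tuple[np.ndarray, float]:
    """Deterministic multistart local optimization; the known-optimum oracle.

    Runs a derivative-free local optimizer from ``n_starts`` seeded uniform
    starting points inside the bounds and returns the best (x, f) found.
    Independent of the metaheuristics in this package, so it serves as the
    reference for the fixed-dimension optima.
    """
    rng = np.random.default_rng(seed)
    starts = rng.uniform(fn.lower_bound, fn.upper_bound, size=(n_starts, fn.dimension))
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = minimize(
            lambda x: fn.evaluate(np.clip(x, fn.lower_bound, fn.upper_bound)),
            x0,
            method=method,
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
        )
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, fn.lower_bound, fn.upper_bound), float(res.fun)
    return best_x, best_f
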