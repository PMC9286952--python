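"""Metaheuristic tuning of the DBN's learning rate and batch size.

The two hyperparameters are encoded as a point in the unit square: the
first coordinate maps log-uniformly onto the learning-rate range, the
second linearly onto the integer batch-size range (nearest-integer
decoding). The optimizer minimizes the DBN's classification error rate on
an inner validation split (fitness = 1 - error rate, reported as accuracy).

Evaluation protocol: stratified k-fold cross-validation (default 10). Each
outer fold is held out as the test set; the remainder is split once more
into a training part and an inner validation part that alone drives the
search; the winning (alpha, beta) retrains on the whole remainder and is
scored on the held-out fold. The held-out fold never reaches a fitness
evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .dbn import DbnConfig, predict, train_dbn
from .mrmr import FeatureTable
from .registry import get_optimizer

__all__ = [
    "SearchSpace",
    "CvProtocol",
    "FoldResult",
    "HyperoptReport",
    "fitness",
    "optimize_hyperparams",
]


@dataclass(frozen=True)
class SearchSpace:
    """2-D continuous encoding of (learning rate alpha, batch size beta).

    ``alpha`` is searched on a log scale over ``alpha_range``; ``beta`` by
    rounding a linear coordinate over the integer ``beta_range``. Decoding
    clips out-of-box coordinates, so it is total and idempotent in effect.
    """

    alpha_range: tuple[float, float] = (0.001, 0.5)
    beta_range: tuple[int, int] = (4, 64)

    def __post_init__(self):
        if not (0 < self.alpha_range[0] <= self.alpha_range[1]):
            raise ValueError("alpha_range must satisfy 0 < low <= high")
        if not (1 <= self.beta_range[0] <= self.beta_range[1]):
            raise ValueError("beta_range must satisfy 1 <= low <= high")

    @property
    def bounds(self) -> np.ndarray:
        """Optimizer box: the unit square."""
        return np.array([[0.0, 1.0], [0.0, 1.0]])

    def decode(self, vector: Sequence[float]) -> tuple[float, int]:
        z = np.clip(np.asarray(vector, dtype=float), 0.0, 1.0)
        lo, hi = self.alpha_range
        alpha = float(10 ** (np.log10(lo) + z[0] * (np.log10(hi) - np.log10(lo))))
        blo, bhi = self.beta_range
        beta = int(np.clip(np.rint(blo + z[1] * (bhi - blo)), blo, bhi))
        return alpha, beta

    def encode(self, alpha: float, beta: int) -> np.ndarray:
        lo, hi = self.alpha_range
        za = 0.0 if hi == lo else (np.log10(alpha) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
        blo, bhi = self.beta_range
        zb = 0.0 if bhi == blo else (beta - blo) / (bhi - blo)
        return np.clip(np.array([za, zb]), 0.0, 1.0)


@dataclass(frozen=True)
class CvProtocol:
    """Stratified k-fold evaluation protocol."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0
    inner_validation_fraction: float = 0.2

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0.0 < self.inner_validation_fraction < 1.0:
            raise ValueError("inner_validation_fraction must lie in (0, 1)")


@dataclass
class FoldResult:
    fold: int
    alpha: float
    beta: int
    test_accuracy: float
    search_accuracy: float
    test_indices: np.ndarray = field(repr=False)
    train_indices: np.ndarray = field(repr=False)


@dataclass
class HyperoptReport:
    folds: list[FoldResult]
    mean_accuracy: float
    optimizer: str
    space: SearchSpace
    cv: CvProtocol
    dbn_config: DbnConfig

    def to_dict(self) -> dict:
        return {
            "optimizer": self.optimizer,
            "mean_accuracy": self.mean_accuracy,
            "folds": [
                {"fold": f.fold, "alpha": f.alpha, "beta": f.beta,
                 "test_accuracy": f.test_accuracy, "search_accuracy": f.search_accuracy}
                for f in self.folds
            ],
            "n_folds": self.cv.n_folds,
            "seed": self.cv.seed,
        }


def _fit_config(dbn_config: DbnConfig, alpha: float, beta: int, n_train: int, seed: int) -> DbnConfig:
    if beta > n_train:
        warnings.warn(f"batch size {beta} exceeds fold size {n_train}; clipping")
        beta = n_train
    return replace(dbn_config, learning_rate=alpha, batch_size=beta, seed=seed)


def fitness(
    candidate: Sequence[float],
    train_split: tuple[np.ndarray, np.ndarray],
    inner_val_split: tuple[np.ndarray, np.ndarray],
    dbn_config: DbnConfig,
    space: SearchSpace | None = None,
) -> float:
    """Validation accuracy (1 - error rate) of the decoded candidate.

    Trains a DBN with the decoded (alpha, beta) on ``train_split`` and
    scores it on ``inner_val_split``. The search itself minimizes
    ``1 - fitness``.
    """
    space = space or SearchSpace()
    alpha, beta = space.decode(candidate)
    X_tr, y_tr = train_split
    cfg = _fit_config(dbn_config, alpha, beta, len(y_tr), dbn_config.seed)
    model = train_dbn(X_tr, y_tr, cfg)
    X_val, y_val = inner_val_split
    return float(np.mean(predict(model, X_val) == np.asarray(y_val)))


def optimize_hyperparams(
    table: FeatureTable,
    space: SearchSpace | None = None,
    optimizer: str = "iaoa",
    population_size: int = 20,
    max_iterations: int = 30,
    cv: CvProtocol | None = None,
    dbn_config: DbnConfig | None = None,
) -> HyperoptReport:
    """Tune (alpha, beta) per outer fold and report held-out accuracies.

    Any optimizer registered in :mod:`~iaoadbn.registry` can drive the
    search. Per-fold seeds derive deterministically from the protocol seed,
    and identical decoded candidates are cached within a fold so the
    rounding plateau of beta costs nothing.
    """
    space = space or SearchSpace()
    cv = cv or CvProtocol()
    dbn_config = dbn_config or DbnConfig()
    entry = get_optimizer(optimizer)
    X, y = table.values, table.labels
    if cv.stratified:
        splitter = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
        split_iter = splitter.split(X, y)
    else:
        from sklearn.model_selection import KFold
        splitter = KFold(n_splits=cv.n_folds, shuffle=True, random_state=cv.seed)
        split_iter = splitter.split(X)

    folds: list[FoldResult] = []
    for fold_id, (rest_idx, test_idx) in enumerate(split_iter):
        fold_seed = int((cv.seed * 1000003 + fold_id * 7919 + 17) % (2**31 - 1))
        tr_idx, val_idx = train_test_split(
            rest_idx,
            test_size=cv.inner_validation_fraction,
            random_state=fold_seed,
            stratify=y[rest_idx] if cv.stratified else None,
        )
        train_split = (X[tr_idx], y[tr_idx])
        val_split = (X[val_idx], y[val_idx])
        cache: dict[tuple[float, int], float] = {}

        def error_rates(candidates: np.ndarray) -> np.ndarray:
            out = np.empty(candidates.shape[0])
            for i, cand in enumerate(candidates):
                key = space.decode(cand)
                if key not in cache:
                    cfg = replace(dbn_config, seed=fold_seed)
                    cache[key] = fitness(cand, train_split, val_split, cfg, space)
                out[i] = 1.0 - cache[key]
            return out

        config = entry.config_factory(
            bounds=space.bounds,
            population_size=population_size,
            max_iterations=max_iterations,
            seed=fold_seed,
        )
        result = entry.optimize(error_rates, config)
        alpha, beta = space.decode(result.best_position)
        final_cfg = _fit_config(dbn_config, alpha, beta, len(rest_idx), fold_seed)
        model = train_dbn(X[rest_idx], y[rest_idx], final_cfg)
        acc = float(np.mean(predict(model, X[test_idx]) == y[test_idx]))
        folds.append(FoldResult(
            fold=fold_id, alpha=alpha, beta=beta, test_accuracy=acc,
            search_accuracy=1.0 - result.best_fitness,
            test_indices=np.asarray(test_idx), train_indices=np.asarray(rest_idx),
        ))
    mean_acc = float(np.mean([f.test_accuracy for f in folds]))
    return HyperoptReport(folds=folds, mean_accuracy=mean_acc, optimizer=entry.name,
                         space=space, cv=cv, dbn_config=dbn_config)
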