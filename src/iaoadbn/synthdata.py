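"""Seeded generators of synthetic tabular cohorts and toy classification sets.

The flagship preset emulates a 298-patient esophageal squamous cell
carcinoma (ESCC) cohort: 17 blood indicators plus age drawn from truncated
normals matching published marginal summary statistics, tumor staging
columns (T, N, TNM) drawn from the published category proportions, and a
binary five-year-survival label planted through a logistic score over 11
designated signal indicators with an exact 147/151 positive/negative split.

The real cohort it stands in for is private, so no claim is made that the
joint distribution is realistic — indicators are independent by default (an
optional correlation matrix activates a Gaussian copula), and only the
marginals and the label mechanism are controlled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.stats import norm, truncnorm

from .mrmr import FeatureTable

__all__ = [
    "IndicatorSpec",
    "CohortSpec",
    "load_preset",
    "escc_spec",
    "generate_cohort",
    "generate_blobs",
]


@dataclass(frozen=True)
class IndicatorSpec:
    """Target marginal summary of one continuous indicator."""

    name: str
    mean: float
    sd: float
    min: float
    max: float


@dataclass
class CohortSpec:
    """Distributional recipe for a synthetic cohort."""

    n_patients: int
    indicators: list[IndicatorSpec]
    categoricals: dict[str, tuple[list[int], list[int]]]  # name -> (values, counts)
    signal_coefficients: dict[str, float]
    logistic_scale: float = 5.5
    target_positive_count: int | None = None
    label_name: str = "survival5y"
    seed: int = 0
    correlation: np.ndarray | None = field(default=None, repr=False)

    @property
    def signal_features(self) -> list[str]:
        return list(self.signal_coefficients)

    @property
    def feature_names(self) -> list[str]:
        return [ind.name for ind in self.indicators] + list(self.categoricals)


def load_preset(name: str = "escc") -> CohortSpec:
    """Load a shipped YAML preset into a :class:`CohortSpec`."""
    ref = importlib.resources.files("iaoadbn") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"unknown preset {name!r}")
    raw = yaml.safe_load(ref.read_text())
    return CohortSpec(
        n_patients=int(raw["n_patients"]),
        indicators=[IndicatorSpec(d["name"], d["mean"], d["sd"], d["min"], d["max"])
                    for d in raw["indicators"]],
        categoricals={k: (list(v["values"]), list(v["counts"]))
                      for k, v in raw["categoricals"].items()},
        signal_coefficients={k: float(v) for k, v in raw["signal"].items()},
        logistic_scale=float(raw["logistic_scale"]),
        target_positive_count=raw.get("target_positive_count"),
        label_name=raw.get("label", "survival5y"),
    )


def escc_spec(n: int = 298, seed: int = 0) -> CohortSpec:
    """The ESCC preset, optionally rescaled to ``n`` patients.

    The exact positive-label count scales proportionally with ``n`` (147 of
    298 at the default size).
    """
    spec = load_preset("escc")
    if n != spec.n_patients:
        spec.target_positive_count = int(round(n * spec.target_positive_count / spec.n_patients))
        spec.n_patients = n
    spec.seed = seed
    return spec


@lru_cache(maxsize=256)
def _calibrate_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Find (loc, scale) whose [lo, hi]-truncated normal best matches the
    target mean and sd (analytic moment matching, relative least squares).

    For boundary-skewed indicators (e.g. a count piled up at 0 with sd above
    its mean) the exact target is infeasible for this family and the closest
    achievable moments are used.
    """
    if lo >= hi:
        raise ValueError(f"infeasible truncation: min {lo} >= max {hi}")

    def moments(loc, scale):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), float(np.sqrt(v))

    def objective(p):
        loc, log_scale = p
        scale = np.exp(np.clip(log_scale, -20, 20))
        with np.errstate(all="ignore"):
            m, s = moments(loc, scale)
        if not (np.isfinite(m) and np.isfinite(s)):
            return 1e12
        ref = max(sd, 1e-9)
        return ((m - mean) / ref) ** 2 + ((s - sd) / ref) ** 2

    best = None
    for loc0, scale0 in [(mean, sd), (lo - sd, 2 * sd), (mean, 3 * sd), (lo - 3 * sd, 4 * sd)]:
        res = minimize(objective, [loc0, np.log(max(scale0, 1e-9))], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return float(best.x[0]), float(np.exp(best.x[1]))


def _sample_indicators(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_patients
    k = len(spec.indicators)
    params = [(_calibrate_truncnorm(ind.mean, ind.sd, ind.min, ind.max), ind)
              for ind in spec.indicators]
    X = np.empty((n, k))
    if spec.correlation is not None:
        # Gaussian copula: correlated uniforms pushed through each marginal ppf
        C = np.asarray(spec.correlation, dtype=float)
        if C.shape != (k, k):
            raise ValueError(f"correlation matrix must be {k}x{k}")
        z = rng.multivariate_normal(np.zeros(k), C, size=n, method="cholesky")
        u = norm.cdf(z)
        for j, ((loc, scale), ind) in enumerate(params):
            a, b = (ind.min - loc) / scale, (ind.max - loc) / scale
            X[:, j] = truncnorm.ppf(u[:, j], a, b, loc=loc, scale=scale)
    else:
        # stratified (Latin-hypercube) inverse-CDF draws per column: same
        # marginal law as iid sampling but with sampling error on the
        # empirical mean/sd of order 1/n instead of 1/sqrt(n)
        for j, ((loc, scale), ind) in enumerate(params):
            a, b = (ind.min - loc) / scale, (ind.max - loc) / scale
            u = (rng.permutation(n) + rng.random(n)) / n
            X[:, j] = truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    return np.clip(X, [i.min for i in spec.indicators], [i.max for i in spec.indicators])


def _plant_labels(spec: CohortSpec, values: np.ndarray, names: list[str],
                  rng: np.random.Generator) -> np.ndarray:
    n = values.shape[0]
    score = np.zeros(n)
    for feat, coef in spec.signal_coefficients.items():
        col = values[:, names.index(feat)]
        sd = col.std()
        z = (col - col.mean()) / (sd if sd > 0 else 1.0)
        score += coef * z
    score -= score.mean()
    sd = score.std()
    if sd > 0:
        score *= spec.logistic_scale / sd
    p = 1.0 / (1.0 + np.exp(-score))
    labels = (rng.random(n) < p).astype(int)
    if spec.target_positive_count is not None:
        target = int(spec.target_positive_count)
        if not 0 <= target <= n:
            raise ValueError(f"target_positive_count {target} infeasible for n={n}")
        # flip the labels whose flip is least improbable under p
        order = np.argsort(p, kind="stable")
        while labels.sum() > target:
            for i in order:              # demote the least probable positives
                if labels[i] == 1:
                    labels[i] = 0
                    break
        while labels.sum() < target:
            for i in order[::-1]:        # promote the most probable negatives
                if labels[i] == 0:
                    labels[i] = 1
                    break
    return labels


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> FeatureTable:
    """Draw one cohort from the recipe; reproducible from the seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = spec.feature_names
    kinds = ["continuous"] * len(spec.indicators) + ["discrete"] * len(spec.categoricals)
    if spec.n_patients == 0:
        empty = np.empty((0, len(names)))
        return FeatureTable(empty, names, np.empty(0, dtype=int), kinds)
    cont = _sample_indicators(spec, rng)
    cat_cols = []
    for values, counts in spec.categoricals.values():
        probs = np.asarray(counts, dtype=float)
        probs /= probs.sum()
        cat_cols.append(rng.choice(values, size=spec.n_patients, p=probs))
    values = np.column_stack([cont] + cat_cols) if cat_cols else cont
    labels = _plant_labels(spec, values, names, rng)
    return FeatureTable(values, names, labels, kinds)


def generate_blobs(n: int, d: int, separation: float, seed: int = 0) -> FeatureTable:
    """Two spherical Gaussian clusters (unit sd) at centroid distance
    ``separation``, with exactly balanced binary labels."""
    if n < 1 or d < 1:
        raise ValueError("n and d must be positive")
    rng = np.random.default_rng(seed)
    labels = np.zeros(n, dtype=int)
    labels[: n // 2] = 1
    rng.shuffle(labels)
    centers = np.zeros((2, d))
    centers[1, 0] = separation
    X = rng.normal(size=(n, d)) + centers[labels]
    return FeatureTable(X, [f"x{j + 1}" for j in range(d)], labels, ["continuous"] * d)
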