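"""Minimum-redundancy maximum-relevance (MRMR) feature ranking.

Relevance of a feature set S to the binary label C is the mean mutual
information D = (1/|S|) sum_i I(x_i; C); redundancy is the normalized
pairwise sum R = (1/|S|^2) sum_ij I(x_i; x_j) (self-pairs included by
default, as the double sum is written). Features are ranked greedily:

* step 1 picks the feature with the largest I(x; C);
* step 2 picks the feature whose addition minimizes the redundancy of the
  selected pair (pure minimum-redundancy step);
* steps 3+ maximize the difference criterion Phi = D - R of the augmented set.

Mutual information is the plug-in estimate (in bits) from the contingency
table of discretized columns; continuous columns are split into
equal-frequency bins (default 10).

The incremental-subset procedure wraps the ranking: for each prefix of the
ranking it scores a small feedforward classifier by stratified 10-fold
cross-validation and returns the smallest prefix attaining the maximum
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "FeatureTable",
    "MrmrRanking",
    "mutual_information",
    "relevance",
    "redundancy",
    "rank_features",
    "incremental_subset_accuracy",
]

DEFAULT_BINS = 10


@dataclass
class FeatureTable:
    """Samples-by-features matrix with named columns and a binary label."""

    values: np.ndarray                 # (n_samples, n_features)
    feature_names: list[str]
    labels: np.ndarray                 # (n_samples,) in {0, 1}
    feature_kinds: list[str] = field(default_factory=list)  # "discrete" | "continuous"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels disagree on the number of samples")
        if 0 < self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples (or 0 for an empty table)")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must name every column")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("values contain missing or non-finite entries")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(int)
        if not self.feature_kinds:
            self.feature_kinds = [
                "discrete" if self._looks_discrete(self.values[:, j]) else "continuous"
                for j in range(self.values.shape[1])
            ]
        if len(self.feature_kinds) != len(self.feature_names):
            raise ValueError("feature_kinds must cover every feature")

    @staticmethod
    def _looks_discrete(col: np.ndarray, max_levels: int = DEFAULT_BINS) -> bool:
        u = np.unique(col)
        return len(u) <= max_levels and np.allclose(u, np.round(u))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name_or_index) -> np.ndarray:
        j = name_or_index if isinstance(name_or_index, (int, np.integer)) \
            else self.feature_names.index(name_or_index)
        return self.values[:, j]

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            self.values[:, idx], list(names), self.labels,
            [self.feature_kinds[j] for j in idx],
        )

    def to_dataframe(self, label_name: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_name] = self.labels
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str, impute: bool = False) -> "FeatureTable":
        if label not in df.columns:
            raise KeyError(f"label column {label!r} not found in {list(df.columns)}")
        features = df.drop(columns=[label])
        if features.isna().any().any():
            if not impute:
                bad = features.columns[features.isna().any()].tolist()
                raise ValueError(f"missing values in columns {bad}; pass impute=True to median-fill")
            features = features.fillna(features.median())
        return cls(features.to_numpy(dtype=float), list(features.columns),
                   df[label].to_numpy())

    @classmethod
    def from_csv(cls, path, label: str, impute: bool = False) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path), label, impute=impute)


@dataclass
class MrmrRanking:
    """Greedy ranking with the per-step relevance D, redundancy R and score
    Phi = D - R of the selected set after each pick."""

    features: list[str]
    indices: list[int]
    relevance: np.ndarray
    redundancy: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.features)


def _discretize(x: np.ndarray, kind: str, bins: int) -> np.ndarray:
    """Map a column to integer codes: identity levels if discrete, otherwise
    equal-frequency bins (duplicate quantile edges collapsed)."""
    x = np.asarray(x, dtype=float)
    if kind == "discrete" or len(np.unique(x)) <= bins:
        _, codes = np.unique(x, return_inverse=True)
        return codes
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = DEFAULT_BINS,
    x_kind: str = "continuous",
    y_kind: str = "continuous",
) -> float:
    """Plug-in mutual information I(x; y) in bits from binned contingency."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with at least 2 samples")
    cx = _discretize(x, x_kind, bins)
    cy = _discretize(y, y_kind, bins)
    return float(mutual_info_score(cx, cy)) / np.log(2)


class _MiCache:
    """Pairwise and feature-label MI for one table, computed on demand."""

    def __init__(self, table: FeatureTable, bins: int):
        self.table = table
        self.bins = bins
        self.codes = [
            _discretize(table.values[:, j], table.feature_kinds[j], bins)
            for j in range(table.n_features)
        ]
        self.label_codes = table.labels
        self._pair: dict[tuple[int, int], float] = {}
        self._rel: dict[int, float] = {}

    def pair(self, i: int, j: int) -> float:
        key = (i, j) if i <= j else (j, i)
        if key not in self._pair:
            self._pair[key] = float(mutual_info_score(self.codes[i], self.codes[j])) / np.log(2)
        return self._pair[key]

    def label(self, i: int) -> float:
        if i not in self._rel:
            self._rel[i] = float(mutual_info_score(self.codes[i], self.label_codes)) / np.log(2)
        return self._rel[i]

    def relevance_of(self, idx: Sequence[int]) -> float:
        return float(np.mean([self.label(i) for i in idx]))

    def redundancy_of(self, idx: Sequence[int], include_self: bool) -> float:
        total = 0.0
        for a in idx:
            for b in idx:
                if a == b and not include_self:
                    continue
                total += self.pair(a, b)
        return total / len(idx) ** 2


def relevance(table: FeatureTable, subset: Sequence[str], bins: int = DEFAULT_BINS) -> float:
    """Mean mutual information between the subset's features and the label."""
    if not subset:
        raise ValueError("relevance of an empty feature set is undefined")
    cache = _MiCache(table, bins)
    return cache.relevance_of([table.feature_names.index(n) for n in subset])


def redundancy(
    table: FeatureTable,
    subset: Sequence[str],
    bins: int = DEFAULT_BINS,
    include_self: bool = True,
) -> float:
    """Normalized pairwise mutual information within the subset.

    The double sum runs over all ordered pairs; ``include_self=False`` drops
    the diagonal entropy terms.
    """
    if not subset:
        raise ValueError("redundancy of an empty feature set is undefined")
    cache = _MiCache(table, bins)
    return cache.redundancy_of([table.feature_names.index(n) for n in subset], include_self)


def rank_features(
    table: FeatureTable,
    k: int | None = None,
    bins: int = DEFAULT_BINS,
    include_self: bool = True,
    step2: str = "paper",
) -> MrmrRanking:
    """Greedy MRMR ranking of the top ``k`` features (all features if None).

    ``step2="paper"`` applies a pure minimum-redundancy rule for the second
    pick; ``step2="mid"`` uses the Phi = D - R criterion from the second
    pick onward. Ties always break toward the lower column index.
    """
    if k is None:
        k = table.n_features
    if not 0 <= k <= table.n_features:
        raise ValueError(f"k must lie in [0, {table.n_features}]")
    if step2 not in ("paper", "mid"):
        raise ValueError("step2 must be 'paper' or 'mid'")
    cache = _MiCache(table, bins)
    selected: list[int] = []
    rel_steps, red_steps, phi_steps = [], [], []
    remaining = list(range(table.n_features))
    for step in range(k):
        if step == 0:
            crit = [cache.label(j) for j in remaining]
            pick = remaining[int(np.argmax(crit))]
        elif step == 1 and step2 == "paper":
            crit = [cache.redundancy_of(selected + [j], include_self) for j in remaining]
            pick = remaining[int(np.argmin(crit))]
        else:
            crit = [
                cache.relevance_of(selected + [j])
                - cache.redundancy_of(selected + [j], include_self)
                for j in remaining
            ]
            pick = remaining[int(np.argmax(crit))]
        selected.append(pick)
        remaining.remove(pick)
        rel_steps.append(cache.relevance_of(selected))
        red_steps.append(cache.redundancy_of(selected, include_self))
        phi_steps.append(rel_steps[-1] - red_steps[-1])
    return MrmrRanking(
        features=[table.feature_names[j] for j in selected],
        indices=selected,
        relevance=np.asarray(rel_steps),
        redundancy=np.asarray(red_steps),
        scores=np.asarray(phi_steps),
    )


def incremental_subset_accuracy(
    table: FeatureTable,
    ranking: MrmrRanking,
    classifier_config: dict | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, int]:
    """Cross-validated accuracy of each ranking prefix; optimal prefix size.

    For k = 1..n_features the top-k ranked features are scored with a small
    single-hidden-layer feedforward classifier (16 units) under stratified
    ``n_folds``-fold cross-validation. Returns the per-k mean-accuracy curve
    and the smallest k attaining its maximum.
    """
    if len(ranking) != table.n_features:
        raise ValueError("ranking must cover all features of the table")
    params = dict(hidden_layer_sizes=(16,), solver="lbfgs", max_iter=500,
                  random_state=seed)
    params.update(classifier_config or {})
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    curve = np.empty(table.n_features)
    for k in range(1, table.n_features + 1):
        X = table.values[:, ranking.indices[:k]]
        clf = make_pipeline(MinMaxScaler(), MLPClassifier(**params))
        curve[k - 1] = cross_val_score(clf, X, table.labels, cv=cv).mean()
    optimal_k = int(np.argmax(curve)) + 1  # argmax returns the first maximum
    return curve, optimal_k
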