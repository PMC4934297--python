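"""The wrapper criterion: kNN accuracy on a held-out validation half.

A candidate feature subset is scored by classifying every validation
pattern with a k-nearest-neighbor vote among the reference (classifier-
construction) patterns, using only the subset's feature columns.  All tie
situations are resolved deterministically so that selection traces are
exactly reproducible:

* distance ties at the k-th position — lower reference-pattern index wins;
* vote ties — the label of the single nearest neighbor wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datamodel import FeatureSubset, FeatureTable, SplitSpec, as_indices

__all__ = [
    "CriterionConfig",
    "CriterionValue",
    "knn_classify",
    "evaluate_subset",
    "SubsetEvaluator",
]


@dataclass(frozen=True)
class CriterionConfig:
    """kNN criterion settings: neighbor count, metric, and the data split."""

    k: int = 3
    metric: str = "euclidean"
    split: SplitSpec = field(default_factory=SplitSpec)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")


@dataclass(frozen=True)
class CriterionValue:
    """An accuracy estimate together with the number of patterns it counted."""

    accuracy: float
    n_evaluated: int

    @property
    def n_correct(self) -> int:
        return int(round(self.accuracy * self.n_evaluated))


def _vote(codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Majority vote per row of ``codes`` (n_queries x k); ties -> column 0."""
    n_q, k = codes.shape
    counts = np.zeros((n_q, n_classes), dtype=int)
    rows = np.repeat(np.arange(n_q), k)
    np.add.at(counts, (rows, codes.ravel()), 1)
    winner = counts.argmax(axis=1)
    top = counts.max(axis=1)
    # vote tie: fall back to the label of the single nearest neighbor
    tied = (counts == top[:, None]).sum(axis=1) > 1
    winner[tied] = codes[tied, 0]
    return winner


def _predict(ref_values: np.ndarray, ref_codes: np.ndarray, n_classes: int,
             queries: np.ndarray, k: int, metric: str) -> np.ndarray:
    if k > ref_values.shape[0]:
        raise ValueError(
            f"k={k} exceeds the {ref_values.shape[0]} reference patterns"
        )
    d = cdist(queries, ref_values, metric=metric)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]  # stable: index tie-break
    return _vote(ref_codes[order], n_classes)


def knn_classify(reference: FeatureTable, query_pattern: Sequence[float],
                 subset: FeatureSubset | Iterable[int],
                 config: CriterionConfig | None = None):
    """Classify one pattern by kNN vote among the reference patterns,
    restricted to the subset's feature columns."""
    config = config or CriterionConfig()
    idx = np.asarray(as_indices(subset), dtype=int)
    if len(idx) == 0:
        raise ValueError("cannot classify with an empty feature subset")
    classes, codes = np.unique(reference.labels, return_inverse=True)
    q = np.asarray(query_pattern, dtype=float).reshape(1, -1)[:, idx]
    pred = _predict(reference.values[:, idx], codes, len(classes),
                    q, config.k, config.metric)
    return classes[pred[0]]


def evaluate_subset(train: FeatureTable, validation: FeatureTable,
                    subset: FeatureSubset | Iterable[int],
                    config: CriterionConfig | None = None) -> CriterionValue:
    """Validation accuracy of a subset: the criterion the wrapper maximizes."""
    config = config or CriterionConfig()
    if train.feature_ids != validation.feature_ids:
        raise ValueError("train and validation tables disagree on feature_ids")
    idx = np.asarray(as_indices(subset), dtype=int)
    if len(idx) == 0:
        raise ValueError("cannot evaluate an empty feature subset")
    classes, codes = np.unique(train.labels, return_inverse=True)
    pred = _predict(train.values[:, idx], codes, len(classes),
                    validation.values[:, idx], config.k, config.metric)
    correct = int(np.sum(classes[pred] == validation.labels))
    n = validation.n_patterns
    return CriterionValue(correct / n, n)


class SubsetEvaluator:
    """Memoizing criterion evaluator used by the search drivers.

    For the Euclidean metric, per-feature squared-distance matrices between
    validation and reference patterns are precomputed once; a subset's
    distance matrix is then a sum of slices.  Squared distances preserve both
    the neighbor ordering and the tie structure of Euclidean distances.
    Results are cached by frozenset of indices, so re-evaluating a subset
    visited earlier in the search is free.  The empty subset scores 0 by
    convention (the criterion is undefined on zero features), so the first
    forward step of any search can always succeed.
    """

    def __init__(self, train: FeatureTable, validation: FeatureTable,
                 config: CriterionConfig | None = None):
        self.config = config or CriterionConfig()
        if train.feature_ids != validation.feature_ids:
            raise ValueError("train and validation tables disagree on feature_ids")
        self.train = train
        self.validation = validation
        self.n_features = train.n_features
        self._classes, self._codes = np.unique(train.labels, return_inverse=True)
        self._cache: dict[frozenset[int], CriterionValue] = {}
        if self.config.metric == "euclidean":
            diff = validation.values[:, None, :] - train.values[None, :, :]
            # (n_features, n_val, n_train) stack of per-feature squared distances
            self._d2 = np.ascontiguousarray(np.moveaxis(diff * diff, -1, 0))
        else:
            self._d2 = None

    @property
    def n_evaluations(self) -> int:
        """Number of distinct subsets evaluated so far."""
        return len(self._cache)

    def __call__(self, subset: FeatureSubset | Iterable[int]) -> CriterionValue:
        idx = as_indices(subset)
        if len(idx) == 0:
            return CriterionValue(0.0, self.validation.n_patterns)
        key = frozenset(idx)
        if len(key) != len(idx):
            raise ValueError("subset indices must be unique")
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self._d2 is not None:
            if self.config.k > self.train.n_patterns:
                raise ValueError("k exceeds the number of reference patterns")
            d = self._d2[sorted(key)].sum(axis=0)
            order = np.argsort(d, axis=1, kind="stable")[:, :self.config.k]
            pred = _vote(self._codes[order], len(self._classes))
            correct = int(np.sum(self._classes[pred] == self.validation.labels))
            value = CriterionValue(correct / self.validation.n_patterns,
                                   self.validation.n_patterns)
        else:
            value = evaluate_subset(self.train, self.validation, idx, self.config)
        self._cache[key] = value
        return value
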