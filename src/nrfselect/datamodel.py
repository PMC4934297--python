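"""Labeled feature tables and deterministic train/validation splitting.

A :class:`FeatureTable` is the package's core in-memory container: a dense
numeric matrix of ``n_patterns x n_features`` with one class label per
pattern and one unique string identifier per feature.  Feature order is
meaningful — the neighborhood topology refers to features positionally, so
the column order of the source CSV *is* the chain/grid order.

CSV layout: one header row, one column per feature plus a label column
(default name ``"label"``); one row per pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .criterion import CriterionValue

__all__ = [
    "FeatureTable",
    "FeatureSubset",
    "SplitSpec",
    "load_feature_table",
    "save_feature_table",
    "split_train_validation",
]


@dataclass
class FeatureTable:
    """A labeled pattern-by-feature matrix.

    Parameters
    ----------
    values : ndarray of shape (n_patterns, n_features)
        Dense numeric feature matrix; no missing values allowed.
    labels : ndarray of shape (n_patterns,)
        Class label per pattern (any hashable scalar; stored as object).
    feature_ids : sequence of str
        Unique identifier per feature, in column (= topology) order.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D patterns x features matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise ValueError("need at least one pattern and one feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite (no NaN/inf)")
        if len(self.labels) != n:
            raise ValueError(
                f"labels length {len(self.labels)} != n_patterns {n}"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} != n_features {p}"
            )
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted distinct class labels."""
        return np.unique(self.labels)

    def take_patterns(self, indices: Sequence[int]) -> "FeatureTable":
        """Sub-table with the given pattern rows (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(self.values[idx], self.labels[idx], list(self.feature_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "label") -> "FeatureTable":
        if label_column not in df.columns:
            raise ValueError(
                f"label column {label_column!r} not found; columns are {list(df.columns)}"
            )
        feats = df.drop(columns=[label_column])
        try:
            values = feats.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            bad = [c for c in feats.columns
                   if pd.to_numeric(feats[c], errors="coerce").isna().any()]
            raise ValueError(
                f"non-numeric value in feature column(s) {bad}"
            ) from exc
        if np.isnan(values).any():
            bad = [c for c, has in zip(feats.columns, np.isnan(values).any(axis=0)) if has]
            raise ValueError(f"missing/non-numeric value in feature column(s) {bad}")
        return cls(values, df[label_column].to_numpy(), [str(c) for c in feats.columns])

    def to_dataframe(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df[label_column] = self.labels
        return df


def load_feature_table(path: str | Path, label_column: str = "label") -> FeatureTable:
    """Read a feature table from CSV.

    Column order (minus the label column) defines feature order, which the
    neighborhood topology interprets positionally.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    df = pd.read_csv(path)
    return FeatureTable.from_dataframe(df, label_column=label_column)


def save_feature_table(table: FeatureTable, path: str | Path,
                       label_column: str = "label") -> None:
    """Write a feature table as CSV (round-trips with :func:`load_feature_table`)."""
    table.to_dataframe(label_column).to_csv(path, index=False)


@dataclass(frozen=True)
class SplitSpec:
    """How to split a table into classifier-reference and validation halves.

    ``fraction`` is the share of patterns assigned to the *first* part.
    Stratified splits keep per-class proportions within one pattern of
    ``fraction``; the permutation is a pure function of ``seed``.
    """

    fraction: float = 0.5
    seed: int = 0
    stratified: bool = True


def split_train_validation(table: FeatureTable, spec: SplitSpec
                           ) -> tuple[FeatureTable, FeatureTable]:
    """Partition a table's patterns into two disjoint, exhaustive parts.

    The first part receives ``round(fraction * n)`` patterns (per class when
    stratified). Pattern order within each part follows the original table.
    """
    if not (0.0 < spec.fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {spec.fraction}")
    rng = np.random.default_rng(spec.seed)
    n = table.n_patterns

    def _take(count_from: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        k = int(np.floor(spec.fraction * len(count_from) + 0.5))
        perm = rng.permutation(count_from)
        return np.sort(perm[:k]), np.sort(perm[k:])

    if spec.stratified:
        first_parts, second_parts = [], []
        for cls in table.classes:
            idx = np.flatnonzero(table.labels == cls)
            if len(idx) < 2:
                raise ValueError(
                    f"class {cls!r} has a single pattern; stratified split impossible"
                )
            a, b = _take(idx)
            first_parts.append(a)
            second_parts.append(b)
        first = np.sort(np.concatenate(first_parts))
        second = np.sort(np.concatenate(second_parts))
    else:
        first, second = _take(np.arange(n))
    return table.take_patterns(first), table.take_patterns(second)


@dataclass
class FeatureSubset:
    """An ordered set of selected feature indices with its criterion value.

    ``indices`` preserves acceptance order (the order features entered the
    subset); set semantics apply for membership. ``criterion`` is the kNN
    validation accuracy achieved by this subset, when known.
    """

    indices: tuple[int, ...]
    criterion: Optional["CriterionValue"] = None
    feature_ids: Optional[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.indices = tuple(int(i) for i in self.indices)
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be unique")
        if any(i < 0 for i in self.indices):
            raise ValueError("subset indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i: int) -> bool:
        return i in set(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def ids(self, table: FeatureTable) -> list[str]:
        """Feature identifiers of the subset, resolved against a table."""
        return [table.feature_ids[i] for i in self.indices]


def as_indices(subset: "FeatureSubset | Iterable[int]") -> tuple[int, ...]:
    """Normalize a subset-like argument to a tuple of feature indices."""
    if isinstance(subset, FeatureSubset):
        return subset.indices
    return tuple(int(i) for i in subset)
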