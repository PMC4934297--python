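"""Baseline selectors: information-gain ranking, SFS, and SFFS.

Information gain is the filter baseline: rank features by the reduction in
class entropy after binning the feature, keep the top ``m``.  SFS and SFFS
are wrapper baselines sharing the kNN criterion; SFFS additionally seeds
the neighborhood-relationship search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .criterion import CriterionConfig, SubsetEvaluator
from .datamodel import FeatureSubset, FeatureTable

__all__ = [
    "DiscretizationSpec",
    "information_gain",
    "information_gain_all",
    "ig_select",
    "sfs_select",
    "sffs_select",
]


@dataclass(frozen=True)
class DiscretizationSpec:
    """Binning applied to a continuous feature before entropy computation."""

    n_bins: int = 10
    strategy: Literal["equal_width", "equal_frequency"] = "equal_width"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _bin_codes(column: np.ndarray, spec: DiscretizationSpec) -> np.ndarray:
    lo, hi = column.min(), column.max()
    if lo == hi:
        return np.zeros(len(column), dtype=int)  # constant feature: one bin
    if spec.strategy == "equal_width":
        edges = np.linspace(lo, hi, spec.n_bins + 1)
    elif spec.strategy == "equal_frequency":
        qs = np.quantile(column, np.linspace(0, 1, spec.n_bins + 1))
        edges = np.unique(qs)  # merge degenerate quantile bins
        if len(edges) < 2:
            return np.zeros(len(column), dtype=int)
    else:
        raise ValueError(f"unknown discretization strategy {spec.strategy!r}")
    codes = np.clip(np.digitize(column, edges[1:-1], right=True), 0, len(edges) - 2)
    return codes


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(table: FeatureTable, feature: int,
                     disc: DiscretizationSpec | None = None) -> float:
    """IG of one feature in bits: H(class) - H(class | binned feature)."""
    disc = disc or DiscretizationSpec()
    if len(table.classes) < 2:
        raise ValueError("information gain needs at least two classes")
    _, y = np.unique(table.labels, return_inverse=True)
    codes = _bin_codes(table.values[:, feature], disc)
    h_class = _entropy_bits(np.bincount(y))
    h_cond = 0.0
    n = len(y)
    for b in np.unique(codes):
        mask = codes == b
        h_cond += mask.sum() / n * _entropy_bits(np.bincount(y[mask]))
    return max(h_class - h_cond, 0.0)


def information_gain_all(table: FeatureTable,
                         disc: DiscretizationSpec | None = None) -> np.ndarray:
    """IG of every feature, in feature (column) order."""
    return np.array([information_gain(table, f, disc)
                     for f in range(table.n_features)])


def ig_select(table: FeatureTable, m: int,
              disc: DiscretizationSpec | None = None) -> FeatureSubset:
    """The ``m`` features with highest information gain (ties: lower index)."""
    if not 1 <= m <= table.n_features:
        raise ValueError(f"m must be in [1, {table.n_features}], got {m}")
    gains = information_gain_all(table, disc)
    order = sorted(range(table.n_features), key=lambda f: (-gains[f], f))
    return FeatureSubset(tuple(order[:m]))


def _best_candidate(evaluator: SubsetEvaluator, base: tuple[int, ...],
                    candidates: list[int], removing: bool = False):
    """Best single add (or removal) by criterion; ties -> lower feature index."""
    best_f, best_v = None, None
    for f in candidates:
        trial = tuple(x for x in base if x != f) if removing else base + (f,)
        v = evaluator(trial).accuracy
        if best_v is None or v > best_v:
            best_f, best_v = f, v
    return best_f, best_v


def sfs_select(train: FeatureTable, validation: FeatureTable,
               config: CriterionConfig | None = None,
               evaluator: SubsetEvaluator | None = None) -> FeatureSubset:
    """Sequential forward selection: greedy additions while the criterion
    strictly improves.  The empty subset scores 0, so the first addition
    always succeeds on any non-degenerate table."""
    ev = evaluator or SubsetEvaluator(train, validation, config)
    current: tuple[int, ...] = ()
    cur_val = ev(current).accuracy
    while len(current) < ev.n_features:
        pool = [f for f in range(ev.n_features) if f not in current]
        f, v = _best_candidate(ev, current, pool)
        if v is None or v <= cur_val:
            break
        current += (f,)
        cur_val = v
    return FeatureSubset(current, ev(current))


def sffs_select(train: FeatureTable, validation: FeatureTable,
                config: CriterionConfig | None = None,
                evaluator: SubsetEvaluator | None = None) -> FeatureSubset:
    """Sequential forward floating search.

    Each round performs the greedy forward addition, then conditional
    backward steps: a removal is accepted only while it yields a criterion
    strictly better than the best subset previously recorded at the smaller
    size.  The search keeps per-size records and returns the best subset
    observed anywhere.  It terminates when a full round improves neither the
    best-overall criterion nor any previously visited per-size record — up
    to that point it follows the SFS path whenever SFS is still improving,
    so the result is never worse than SFS on the same inputs.
    """
    ev = evaluator or SubsetEvaluator(train, validation, config)
    n = ev.n_features
    current: tuple[int, ...] = ()
    best_by_size: dict[int, float] = {0: 0.0}
    best_subset_by_size: dict[int, tuple[int, ...]] = {0: ()}
    best_overall, best_subset = 0.0, ()

    def record(sub: tuple[int, ...], v: float) -> bool:
        nonlocal best_overall, best_subset
        k = len(sub)
        improved = False
        if v > best_by_size.get(k, -1.0):
            best_by_size[k] = v
            best_subset_by_size[k] = sub
        if v > best_overall:
            best_overall, best_subset = v, sub
            improved = True
        return improved

    while True:
        improved_round = False
        if len(current) == n:
            break
        pool = [f for f in range(n) if f not in current]
        f, v = _best_candidate(ev, current, pool)
        visited = len(current) + 1 in best_by_size
        prev_best = best_by_size.get(len(current) + 1, -1.0)
        current += (f,)
        improved_round |= record(current, v)
        if visited and v > prev_best:
            improved_round = True
        # conditional backward steps
        while len(current) > 2:
            r, vr = _best_candidate(ev, current, list(current), removing=True)
            if vr > best_by_size.get(len(current) - 1, -1.0):
                current = tuple(x for x in current if x != r)
                improved_round |= record(current, vr)
                improved_round = True
            else:
                break
        if not improved_round:
            break
    return FeatureSubset(best_subset, ev(best_subset))
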