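"""Neighborhood topologies, weight kernels, rankings and pair enumeration.

Features live on a 1-D chain (spectral bands) or a 2-D grid (image
subregions).  A *weight diagram* maps inter-feature distance to an integer
weight; a feature's accumulated weight is the kernel sum over the currently
selected features.  High accumulated weight means "surrounded by selected
neighbors": such unselected features are prioritised for addition, and
selected features with *low* weight (isolated from the rest of the subset)
are prioritised for elimination.

The default chain kernel gives weight 2 to immediate neighbors and 1 at
distance two.  On the grid the same kernel is applied to Chebyshev
(king-move) distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .datamodel import FeatureSubset, as_indices

__all__ = [
    "NeighborhoodTopology",
    "chain",
    "grid",
    "chain_runs",
    "WeightDiagram",
    "WeightAssignment",
    "compute_unselected_weights",
    "compute_selected_weights",
    "rank_by_weight",
    "enumerate_pairs",
]


@dataclass(frozen=True)
class NeighborhoodTopology:
    """Positions of features on a chain or grid, inducing integer distances.

    ``kind`` is ``"chain"`` (positions ``0..n-1``, distance ``|i-j|``) or
    ``"grid"`` (row-major positions on ``rows x cols``, Chebyshev distance).
    """

    kind: Literal["chain", "grid"]
    n_features: int
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("topology needs at least one feature")
        if self.kind == "grid":
            if self.grid_shape is None:
                raise ValueError("grid topology requires grid_shape")
            r, c = self.grid_shape
            if r * c != self.n_features:
                raise ValueError(
                    f"grid_shape {self.grid_shape} incompatible with "
                    f"n_features={self.n_features}"
                )
        elif self.kind != "chain":
            raise ValueError(f"unknown topology kind {self.kind!r}")

    def distance(self, i: int, j: int) -> int:
        """Distance between features ``i`` and ``j`` (symmetric, integer)."""
        self._check(i)
        self._check(j)
        if self.kind == "chain":
            return abs(i - j)
        cols = self.grid_shape[1]  # type: ignore[index]
        ri, ci = divmod(i, cols)
        rj, cj = divmod(j, cols)
        return max(abs(ri - rj), abs(ci - cj))

    def distance_matrix(self) -> np.ndarray:
        """Full ``n x n`` integer distance matrix."""
        if self.kind == "chain":
            pos = np.arange(self.n_features)
            return np.abs(pos[:, None] - pos[None, :])
        cols = self.grid_shape[1]  # type: ignore[index]
        r, c = np.divmod(np.arange(self.n_features), cols)
        return np.maximum(
            np.abs(r[:, None] - r[None, :]), np.abs(c[:, None] - c[None, :])
        )

    def _check(self, i: int) -> None:
        if not 0 <= i < self.n_features:
            raise IndexError(
                f"feature index {i} out of range for {self.n_features} features"
            )


def chain_runs(indices: Iterable[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive chain positions, as half-open ranges."""
    idx = sorted(set(indices))
    runs: list[tuple[int, int]] = []
    for i in idx:
        if runs and i == runs[-1][1]:
            runs[-1] = (runs[-1][0], i + 1)
        else:
            runs.append((i, i + 1))
    return runs


def chain(n_features: int) -> NeighborhoodTopology:
    """1-D chain topology over ``n_features`` positions."""
    return NeighborhoodTopology("chain", n_features)


def grid(rows: int, cols: int) -> NeighborhoodTopology:
    """2-D grid topology (row-major feature order, Chebyshev distance)."""
    return NeighborhoodTopology("grid", rows * cols, (rows, cols))


@dataclass(frozen=True)
class WeightDiagram:
    """Distance -> weight kernel with finite support.

    The default kernel (chain and grid alike) is ``{1: 2, 2: 1}``: immediate
    neighbors contribute 2, next-nearest contribute 1, farther features 0.
    ``kernel[0]`` is never consulted — a feature is not its own neighbor.
    """

    kernel: Mapping[int, int] = field(default_factory=lambda: {1: 2, 2: 1})

    def __post_init__(self) -> None:
        for d, w in self.kernel.items():
            if d < 0 or w < 0:
                raise ValueError("kernel distances and weights must be >= 0")

    @classmethod
    def default(cls) -> "WeightDiagram":
        return cls()

    def weight(self, distance: int) -> int:
        return int(self.kernel.get(int(distance), 0))

    def lookup_table(self, max_distance: int) -> np.ndarray:
        """Vector ``t`` with ``t[d] = weight(d)`` for ``d = 0..max_distance``."""
        t = np.zeros(max_distance + 1, dtype=int)
        for d, w in self.kernel.items():
            if 0 <= d <= max_distance:
                t[d] = w
        return t


@dataclass
class WeightAssignment:
    """Accumulated weight per feature, for one scope of the search.

    ``scope`` is ``"unselected"`` (addition-stage weights) or ``"selected"``
    (elimination-stage weights).
    """

    weights: dict[int, int]
    scope: Literal["unselected", "selected"]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


def _kernel_sums(targets: np.ndarray, sources: np.ndarray,
                 topology: NeighborhoodTopology,
                 diagram: WeightDiagram) -> np.ndarray:
    """Sum of kernel(distance(t, s)) over sources, per target."""
    if len(targets) == 0:
        return np.zeros(0, dtype=int)
    dm = topology.distance_matrix()[np.ix_(targets, sources)]
    table = diagram.lookup_table(int(dm.max(initial=0)))
    return table[dm].sum(axis=1)


def compute_unselected_weights(subset: FeatureSubset | Iterable[int],
                               topology: NeighborhoodTopology,
                               diagram: WeightDiagram | None = None
                               ) -> WeightAssignment:
    """Addition-stage weights: for each *unselected* feature, the kernel sum
    over all selected features.  With nothing selected all weights are 0."""
    diagram = diagram or WeightDiagram.default()
    selected = np.asarray(sorted(as_indices(subset)), dtype=int)
    for i in selected:
        topology._check(int(i))
    unselected = np.setdiff1d(np.arange(topology.n_features), selected)
    sums = _kernel_sums(unselected, selected, topology, diagram) \
        if len(selected) else np.zeros(len(unselected), dtype=int)
    return WeightAssignment(
        {int(f): int(w) for f, w in zip(unselected, sums)}, "unselected"
    )


def compute_selected_weights(subset: FeatureSubset | Iterable[int],
                             topology: NeighborhoodTopology,
                             diagram: WeightDiagram | None = None
                             ) -> WeightAssignment:
    """Elimination-stage weights: for each *selected* feature, the kernel sum
    over the other selected features (self excluded)."""
    diagram = diagram or WeightDiagram.default()
    selected = np.asarray(sorted(as_indices(subset)), dtype=int)
    if len(selected) == 0:
        raise ValueError("selected-weight computation needs a non-empty subset")
    for i in selected:
        topology._check(int(i))
    dm = topology.distance_matrix()[np.ix_(selected, selected)]
    table = diagram.lookup_table(int(dm.max(initial=0)))
    contrib = table[dm]
    np.fill_diagonal(contrib, 0)  # a feature is not its own neighbor
    sums = contrib.sum(axis=1)
    return WeightAssignment(
        {int(f): int(w) for f, w in zip(selected, sums)}, "selected"
    )


def rank_by_weight(assignment: WeightAssignment,
                   order: Literal["descending", "ascending"]
                   ) -> list[tuple[int, int, int]]:
    """Rank features by weight with competition ranking.

    Equal weights share a rank (1224-style); traversal order among ties is by
    lower feature index.  Returns ``(feature, weight, rank)`` triples in
    traversal order.
    """
    if not assignment.weights:
        raise ValueError("cannot rank an empty weight assignment")
    if order not in ("descending", "ascending"):
        raise ValueError(f"unknown order {order!r}")
    sign = -1 if order == "descending" else 1
    items = sorted(assignment.weights.items(), key=lambda fw: (sign * fw[1], fw[0]))
    ranked: list[tuple[int, int, int]] = []
    rank = 0
    prev_w: int | None = None
    for pos, (f, w) in enumerate(items, start=1):
        if w != prev_w:
            rank = pos  # competition ranking: rank jumps past the tie block
            prev_w = w
        ranked.append((f, w, rank))
    return ranked


def enumerate_pairs(assignment: WeightAssignment, threshold: int,
                    mode: Literal["at_least", "below"]
                    ) -> list[tuple[tuple[int, int], int]]:
    """Enumerate feature pairs by weight-value sum against a threshold.

    ``at_least`` keeps pairs with ``sum >= threshold``, best (largest sum)
    first — the addition-stage candidate list.  ``below`` keeps pairs with
    ``sum < threshold``, smallest sum first — the elimination-stage list.
    Ties are ordered by lexicographic index pair.
    """
    if len(assignment.weights) < 2:
        raise ValueError("pair enumeration needs at least two features")
    if mode not in ("at_least", "below"):
        raise ValueError(f"unknown mode {mode!r}")
    feats = sorted(assignment.weights)
    pairs = []
    for i, j in itertools.combinations(feats, 2):
        s = assignment.weights[i] + assignment.weights[j]
        if (mode == "at_least" and s >= threshold) or (mode == "below" and s < threshold):
            pairs.append(((i, j), s))
    sign = -1 if mode == "at_least" else 1
    pairs.sort(key=lambda ps: (sign * ps[1], ps[0]))
    return pairs
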