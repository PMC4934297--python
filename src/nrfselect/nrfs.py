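"""Neighborhood-relationship feature selection (NRFS).

The search starts from an SFFS-initialized subset and alternates two
stages driven by the neighborhood weights of :mod:`nrfselect.topology`:

* **add stage** — unselected features are tried in descending-weight order
  and accepted when the kNN criterion does not decrease; when no single
  addition is accepted, *pairs* of unselected features whose weight sum
  reaches ``t_add`` are tried in descending-sum order under the same rule.
  Any acceptance triggers a weight recomputation.
* **eliminate stage** — selected features are tried in ascending-weight
  order and removed only on a *strict* criterion improvement; when no
  single elimination is accepted, pairs of selected features with weight
  sum below ``t_del`` are tried in ascending-sum order, again requiring
  strict improvement.

Every attempted decision (accepted or not) is logged to a
:class:`SelectionTrace`; replaying the accepted records from the initial
subset reproduces the final subset exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .baselines import sffs_select
from .criterion import CriterionConfig, SubsetEvaluator
from .datamodel import FeatureSubset, FeatureTable, as_indices
from .topology import (
    NeighborhoodTopology,
    WeightDiagram,
    compute_selected_weights,
    compute_unselected_weights,
    enumerate_pairs,
    rank_by_weight,
)

__all__ = [
    "NRFSConfig",
    "TraceRecord",
    "SelectionTrace",
    "nrfs_add_stage",
    "nrfs_eliminate_stage",
    "nrfs_run",
]


@dataclass(frozen=True)
class NRFSConfig:
    """Thresholds, criterion settings, and topology for an NRFS run.

    ``t_add`` filters pair additions (weight sum must reach it) and
    ``t_del`` filters pair eliminations (weight sum must stay below it).
    With ``loop_stages=True`` the add/eliminate cycle repeats until a full
    pass accepts nothing, instead of the default single pass.
    """

    topology: NeighborhoodTopology
    t_add: int = 7
    t_del: int = 3
    criterion: CriterionConfig = field(default_factory=CriterionConfig)
    diagram: WeightDiagram = field(default_factory=WeightDiagram.default)
    loop_stages: bool = False

    def __post_init__(self) -> None:
        if self.t_add < 0 or self.t_del < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class TraceRecord:
    """One attempted decision: which feature(s), their weights, the
    criterion before/after, and whether the move was accepted."""

    stage: str           # "init", "add", "eliminate"
    step: int            # 1 (init), 3/4 (add single/pair), 6/7 (eliminate)
    candidates: tuple[int, ...]
    weights: tuple[int, ...]
    criterion_before: float
    criterion_after: float
    accepted: bool

    def to_json(self) -> str:
        return json.dumps({
            "stage": self.stage, "step": self.step,
            "candidates": list(self.candidates), "weights": list(self.weights),
            "criterion_before": self.criterion_before,
            "criterion_after": self.criterion_after,
            "accepted": self.accepted,
        })

    @classmethod
    def from_json(cls, line: str) -> "TraceRecord":
        d = json.loads(line)
        return cls(d["stage"], d["step"], tuple(d["candidates"]),
                   tuple(d["weights"]), d["criterion_before"],
                   d["criterion_after"], d["accepted"])


@dataclass
class SelectionTrace:
    """Append-only log of every attempted add/eliminate decision."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, record: TraceRecord) -> None:
        self.records.append(record)

    def extend(self, other: "SelectionTrace") -> None:
        self.records.extend(other.records)

    def accepted(self) -> list[TraceRecord]:
        return [r for r in self.records if r.accepted]

    def replay(self, initial: Iterable[int] | None = None) -> tuple[int, ...]:
        """Re-apply accepted records and return the resulting subset.

        If the trace begins with an ``init`` record its candidates seed the
        subset; otherwise ``initial`` must be given.
        """
        current: list[int] = list(initial) if initial is not None else []
        for rec in self.accepted():
            if rec.stage == "init":
                current = list(rec.candidates)
            elif rec.stage == "add":
                current.extend(rec.candidates)
            elif rec.stage == "eliminate":
                for f in rec.candidates:
                    current.remove(f)
            else:  # pragma: no cover - defensive
                raise ValueError(f"unknown trace stage {rec.stage!r}")
        return tuple(current)

    def save_jsonl(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(r.to_json() + "\n" for r in self.records))

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "SelectionTrace":
        lines = Path(path).read_text().splitlines()
        return cls([TraceRecord.from_json(ln) for ln in lines if ln.strip()])


def _make_evaluator(train: FeatureTable, validation: FeatureTable,
                    config: NRFSConfig,
                    evaluator: Optional[SubsetEvaluator]) -> SubsetEvaluator:
    if evaluator is not None:
        return evaluator
    return SubsetEvaluator(train, validation, config.criterion)


def nrfs_add_stage(subset: FeatureSubset | Iterable[int],
                   train: FeatureTable, validation: FeatureTable,
                   config: NRFSConfig,
                   evaluator: Optional[SubsetEvaluator] = None
                   ) -> tuple[FeatureSubset, SelectionTrace]:
    """Grow the subset by weighted single and pair additions.

    An addition is accepted when the criterion does not decrease (equality
    allowed).  Accepted moves return control to the weight recomputation;
    the stage ends when neither a single nor a pair addition is accepted.
    """
    ev = _make_evaluator(train, validation, config, evaluator)
    current = as_indices(subset)
    cur_val = ev(current).accuracy
    trace = SelectionTrace()
    topo, diagram = config.topology, config.diagram

    while True:
        n_unselected = topo.n_features - len(current)
        if n_unselected == 0:
            break
        wa = compute_unselected_weights(current, topo, diagram)
        accepted = False
        for f, w, _rank in rank_by_weight(wa, "descending"):
            v = ev(current + (f,)).accuracy
            ok = v >= cur_val
            trace.append(TraceRecord("add", 3, (f,), (w,), cur_val, v, ok))
            if ok:
                current += (f,)
                cur_val = v
                accepted = True
                break
        if accepted:
            continue
        if n_unselected >= 2:
            for (i, j), s in enumerate_pairs(wa, config.t_add, "at_least"):
                v = ev(current + (i, j)).accuracy
                ok = v >= cur_val
                trace.append(TraceRecord(
                    "add", 4, (i, j), (wa.weights[i], wa.weights[j]),
                    cur_val, v, ok))
                if ok:
                    current += (i, j)
                    cur_val = v
                    accepted = True
                    break
        if not accepted:
            break
    return FeatureSubset(current, ev(current)), trace


def nrfs_eliminate_stage(subset: FeatureSubset | Iterable[int],
                         train: FeatureTable, validation: FeatureTable,
                         config: NRFSConfig,
                         evaluator: Optional[SubsetEvaluator] = None
                         ) -> tuple[FeatureSubset, SelectionTrace]:
    """Shrink the subset by weighted single and pair eliminations.

    Removals require a strictly better criterion; the subset is never
    emptied.  Accepted moves return control to the weight recomputation;
    the stage ends when neither a single nor a pair elimination is accepted.
    """
    ev = _make_evaluator(train, validation, config, evaluator)
    current = as_indices(subset)
    if len(current) == 0:
        raise ValueError("eliminate stage needs a non-empty subset")
    cur_val = ev(current).accuracy
    trace = SelectionTrace()
    topo, diagram = config.topology, config.diagram

    while True:
        wa = compute_selected_weights(current, topo, diagram)
        accepted = False
        if len(current) >= 2:
            for f, w, _rank in rank_by_weight(wa, "ascending"):
                remaining = tuple(x for x in current if x != f)
                v = ev(remaining).accuracy
                ok = v > cur_val
                trace.append(TraceRecord(
                    "eliminate", 6, (f,), (w,), cur_val, v, ok))
                if ok:
                    current = remaining
                    cur_val = v
                    accepted = True
                    break
        if accepted:
            continue
        if len(current) >= 3:  # pair removal must leave a non-empty subset
            for (i, j), s in enumerate_pairs(wa, config.t_del, "below"):
                remaining = tuple(x for x in current if x not in (i, j))
                v = ev(remaining).accuracy
                ok = v > cur_val
                trace.append(TraceRecord(
                    "eliminate", 7, (i, j), (wa.weights[i], wa.weights[j]),
                    cur_val, v, ok))
                if ok:
                    current = remaining
                    cur_val = v
                    accepted = True
                    break
        if not accepted:
            break
    return FeatureSubset(current, ev(current)), trace


def nrfs_run(train: FeatureTable, validation: FeatureTable,
             config: NRFSConfig,
             evaluator: Optional[SubsetEvaluator] = None
             ) -> tuple[FeatureSubset, SelectionTrace]:
    """Full NRFS: SFFS initialization, then the add and eliminate stages.

    Returns the final subset and the concatenated trace, whose first record
    (stage ``"init"``) holds the SFFS subset and its criterion.  The final
    criterion never falls below the initialization criterion: additions
    never decrease it and eliminations strictly increase it.
    """
    ev = _make_evaluator(train, validation, config, evaluator)
    init = sffs_select(train, validation, config.criterion, evaluator=ev)
    trace = SelectionTrace()
    trace.append(TraceRecord("init", 1, init.indices, (),
                             0.0, init.criterion.accuracy, True))
    current: FeatureSubset = init
    while True:
        before = current.indices
        current, add_tr = nrfs_add_stage(current, train, validation, config, ev)
        trace.extend(add_tr)
        if len(current) > 0:
            current, del_tr = nrfs_eliminate_stage(
                current, train, validation, config, ev)
            trace.extend(del_tr)
        if not config.loop_stages or current.indices == before:
            break
    return current, trace
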