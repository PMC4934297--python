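"""Weight kernels, rankings, pair enumeration, and their brute-force oracles."""

import itertools
import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrfselect import (
    WeightDiagram,
    chain,
    compute_selected_weights,
    compute_unselected_weights,
    enumerate_pairs,
    grid,
    rank_by_weight,
)
from nrfselect.topology import WeightAssignment

LETTER = {c: i for i, c in enumerate(string.ascii_uppercase)}


def brute_force_unselected(selected, topology, diagram):
    """Independent double loop over (unselected, selected) pairs."""
    out = {}
    for f in range(topology.n_features):
        if f in selected:
            continue
        out[f] = sum(diagram.weight(topology.distance(f, s)) for s in selected)
    return out


def brute_force_selected(selected, topology, diagram):
    out = {}
    for f in selected:
        out[f] = sum(diagram.weight(topology.distance(f, s))
                     for s in selected if s != f)
    return out


# --- worked example on the 10-feature chain -------------------------------

def test_unselected_weights_worked_example():
    """Selected {C,D,F,H} on a chain A..J gives the published weight column."""
    wa = compute_unselected_weights([LETTER[c] for c in "CDFH"], chain(10))
    expect = {"A": 1, "B": 3, "E": 5, "G": 4, "I": 2, "J": 1}
    assert {string.ascii_uppercase[f]: w for f, w in wa.weights.items()} == expect


def test_unselected_ranking_worked_example():
    wa = compute_unselected_weights([LETTER[c] for c in "CDFH"], chain(10))
    ranked = rank_by_weight(wa, "descending")
    names = [string.ascii_uppercase[f] for f, _, _ in ranked]
    ranks = [r for _, _, r in ranked]
    assert names == ["E", "G", "B", "I", "A", "J"]
    assert ranks == [1, 2, 3, 4, 5, 5]  # A and J share rank 5


def test_pair_enumeration_worked_example():
    """The top pair candidates at threshold 7 match the published list."""
    wa = compute_unselected_weights([LETTER[c] for c in "CDFH"], chain(10))
    pairs = enumerate_pairs(wa, 7, "at_least")
    top3 = [(tuple(string.ascii_uppercase[i] for i in p), s) for p, s in pairs[:3]]
    assert top3 == [(("E", "G"), 9), (("B", "E"), 8), (("B", "G"), 7)]
    assert all(s >= 7 for _, s in pairs)


def test_selected_weights_worked_example():
    """Selected {C,D,E,F,H}: elimination-stage weights and ascending order."""
    wa = compute_selected_weights([LETTER[c] for c in "CDEFH"], chain(10))
    expect = {"C": 3, "D": 5, "E": 5, "F": 4, "H": 1}
    assert {string.ascii_uppercase[f]: w for f, w in wa.weights.items()} == expect
    ranked = rank_by_weight(wa, "ascending")
    assert [string.ascii_uppercase[f] for f, _, _ in ranked] == list("HCFDE")
    assert [r for _, _, r in ranked] == [1, 2, 3, 4, 4]  # D and E tie


# --- trivial and degenerate cases -----------------------------------------

def test_empty_subset_gives_zero_weights():
    wa = compute_unselected_weights([], chain(6))
    assert set(wa.weights.values()) == {0}
    assert len(wa.weights) == 6


def test_singleton_selected_weight_zero():
    wa = compute_selected_weights([3], chain(8))
    assert wa.weights == {3: 0}


def test_selected_weights_rejects_empty():
    with pytest.raises(ValueError):
        compute_selected_weights([], chain(5))


def test_out_of_range_subset():
    with pytest.raises(IndexError):
        compute_unselected_weights([10], chain(10))


def test_all_equal_weights_share_rank_one():
    wa = WeightAssignment({0: 2, 1: 2, 2: 2}, "unselected")
    ranked = rank_by_weight(wa, "descending")
    assert [(f, r) for f, _, r in ranked] == [(0, 1), (1, 1), (2, 1)]


def test_unreachable_pair_threshold_empty():
    wa = compute_unselected_weights([LETTER[c] for c in "CDFH"], chain(10))
    assert enumerate_pairs(wa, 100, "at_least") == []


def test_grid_distance_is_chebyshev():
    g = grid(4, 4)
    assert g.distance(0, 5) == 1    # diagonal neighbor
    assert g.distance(0, 15) == 3
    assert g.distance(1, 2) == 1
    assert g.distance(0, 8) == 2


def test_grid_shape_mismatch_rejected():
    from nrfselect import NeighborhoodTopology
    with pytest.raises(ValueError):
        NeighborhoodTopology("grid", 10, (3, 3))


# --- property tests against the brute-force oracle ------------------------

@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_chain_weights_match_brute_force(data):
    n = data.draw(st.integers(3, 40))
    selected = data.draw(st.sets(st.integers(0, n - 1), min_size=1, max_size=n))
    topo = chain(n)
    diagram = WeightDiagram.default()
    wa = compute_unselected_weights(selected, topo, diagram)
    assert wa.weights == brute_force_unselected(selected, topo, diagram)
    ws = compute_selected_weights(selected, topo, diagram)
    assert ws.weights == brute_force_selected(selected, topo, diagram)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_grid_weights_match_brute_force(data):
    rows = data.draw(st.integers(2, 7))
    cols = data.draw(st.integers(2, 7))
    n = rows * cols
    selected = data.draw(st.sets(st.integers(0, n - 1), min_size=1, max_size=n))
    topo = grid(rows, cols)
    diagram = WeightDiagram.default()
    wa = compute_unselected_weights(selected, topo, diagram)
    assert wa.weights == brute_force_unselected(selected, topo, diagram)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_chain_reversal_symmetry(data):
    """Relabeling features by reversing the chain reverses the weight vector."""
    n = data.draw(st.integers(3, 30))
    selected = data.draw(st.sets(st.integers(0, n - 1), min_size=1, max_size=n - 1))
    topo = chain(n)
    wa = compute_unselected_weights(selected, topo)
    mirrored = {n - 1 - f for f in selected}
    wb = compute_unselected_weights(mirrored, topo)
    assert {n - 1 - f: w for f, w in wa.weights.items()} == wb.weights


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.data())
def test_pair_enumeration_matches_exhaustive(data):
    weights = data.draw(st.dictionaries(st.integers(0, 20), st.integers(0, 9),
                                        min_size=2, max_size=12))
    threshold = data.draw(st.integers(0, 15))
    wa = WeightAssignment(weights, "unselected")
    got = enumerate_pairs(wa, threshold, "at_least")
    expect = sorted(
        (((i, j), weights[i] + weights[j])
         for i, j in itertools.combinations(sorted(weights), 2)
         if weights[i] + weights[j] >= threshold),
        key=lambda ps: (-ps[1], ps[0]))
    assert got == expect
    below = enumerate_pairs(wa, threshold, "below")
    assert all(s < threshold for _, s in below)
    assert [s for _, s in below] == sorted(s for _, s in below)
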