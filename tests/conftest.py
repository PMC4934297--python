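"""Shared fixtures: small labeled tables with known structure."""

import numpy as np
import pytest

from nrfselect import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(20160614)


@pytest.fixture
def toy_table_aj(rng):
    """12-pattern table with features A..J; A separates the classes."""
    n = 12
    labels = np.array(["x"] * 6 + ["y"] * 6)
    values = rng.normal(0, 1, size=(n, 10))
    values[:, 0] = np.where(labels == "x", -3.0, 3.0) + rng.normal(0, 0.2, n)
    return FeatureTable(values, labels, list("ABCDEFGHIJ"))


@pytest.fixture
def separable_table(rng):
    """2-class table: feature 0 fully informative, features 1-3 pure noise."""
    n = 40
    labels = np.array(["a"] * 20 + ["b"] * 20)
    values = rng.normal(0, 1, size=(n, 4))
    values[:, 0] = np.where(labels == "a", -5.0, 5.0) + rng.normal(0, 0.3, n)
    return FeatureTable(values, labels, ["f0", "f1", "f2", "f3"])
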