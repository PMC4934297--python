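"""Simple selected-feature maps (chain bar, grid heat map)."""

from __future__ import annotations

from typing import Iterable


def plot_chain_selection(selected: Iterable[int], n_features: int, ax=None):
    """Bar map of a chain: selected positions filled, others empty."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    sel = set(selected)
    colors = ["tab:red" if i in sel else "0.85" for i in range(n_features)]
    ax.bar(range(n_features), [1] * n_features, color=colors, width=0.9)
    ax.set_yticks([])
    ax.set_xlabel("feature position")
    return ax


def plot_grid_selection(selected: Iterable[int], shape: tuple[int, int], ax=None):
    """Heat map of a grid: selected cells highlighted."""
    import matplotlib.pyplot as plt
    import numpy as np

    ax = ax or plt.gca()
    mask = np.zeros(shape)
    cols = shape[1]
    for i in selected:
        mask[divmod(i, cols)] = 1
    ax.imshow(mask, cmap="Reds", vmin=0, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
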