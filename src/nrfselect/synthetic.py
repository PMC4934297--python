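"""Planted-relevance synthetic benchmarks for both applications.

Real counterparts of the two data sets (rodent EEG recordings; a scanned
character database) are not redistributable, so these generators emulate
their *structure*: class-discriminative signal concentrated in spatially
contiguous feature regions, which is the premise the neighborhood search
is designed for.

* :func:`generate_eeg_like_dataset` — three vigilance-state analogues
  (AW, SWS, REM) over 32 normalized band powers.  SWS is dominated by a
  low-frequency (delta-like) run; AW and REM share an elevated alpha-like
  run and differ in the level of a gamma-like run (REM higher).  Signal
  lives in contiguous band runs; everything is normalized to sum to one
  like real relative band powers.
* :func:`generate_char_like_dataset` — two character classes drawn as
  random stroke images on a 64x64 canvas, identical in distribution except
  that the second class adds a dense dot strictly inside a contiguous
  "crucial region" of the 16x16 block grid (the dot that distinguishes a
  dog-character from a big-character, in spirit).
* :func:`inject_noise` — the robustness protocol: corrupt a fixed fraction
  of patterns in a fixed number of randomly chosen feature cells.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from skimage.draw import disk, line

from .datamodel import FeatureTable
from .features import char_subregion_features

__all__ = [
    "EEGSynthConfig",
    "NoiseSpec",
    "generate_eeg_like_dataset",
    "generate_char_like_dataset",
    "inject_noise",
    "DEFAULT_REGIONS",
]

# Class profiles over 32 bands of (0, 50] Hz, width 1.5625 Hz.
# Runs are half-open [start, stop) band ranges with a mean elevation:
#   delta-like: bands 0-2 (~0-4.7 Hz), alpha-like: bands 5-7 (~7.8-12.5 Hz),
#   gamma-like: bands 14-21 (~21.9-34.4 Hz).
DELTA_RUN = (0, 3)
ALPHA_RUN = (5, 8)
GAMMA_RUN = (14, 22)
DEFAULT_REGIONS: dict[str, list[tuple[tuple[int, int], float]]] = {
    "AW": [(ALPHA_RUN, 1.2), (GAMMA_RUN, 0.8)],
    "SWS": [(DELTA_RUN, 2.0)],
    "REM": [(ALPHA_RUN, 1.2), (GAMMA_RUN, 1.6)],
}


@dataclass(frozen=True)
class EEGSynthConfig:
    """Configuration of the EEG-like generator.

    Defaults mirror the training-set composition of the motivating study
    (236 AW / 248 SWS / 56 REM epochs, 32 bands) and its qualitative class
    spectra.  ``noise_sd`` is the standard deviation of the additive
    Gaussian band noise before normalization, on the same scale as the
    baseline profile (max 1.5) and the elevations (0.8-2.0).
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"AW": 236, "SWS": 248, "REM": 56})
    n_features: int = 32
    informative_regions: Mapping[str, list[tuple[tuple[int, int], float]]] = \
        field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGIONS.items()})
    noise_sd: float = 0.5
    baseline_decay: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, regions in self.informative_regions.items():
            for (start, stop), elev in regions:
                if not (0 <= start < stop <= self.n_features):
                    raise ValueError(
                        f"region [{start}, {stop}) outside 0..{self.n_features}")
                if elev <= 0:
                    raise ValueError("elevations must be positive")

    @property
    def planted_runs(self) -> list[tuple[int, int]]:
        """Distinct informative band runs across all classes, sorted."""
        runs = {run for regions in self.informative_regions.values()
                for run, _ in regions}
        return sorted(runs)


def _baseline(config: EEGSynthConfig) -> np.ndarray:
    b = np.arange(config.n_features)
    return 0.5 + np.exp(-b / config.baseline_decay)


def generate_eeg_like_dataset(config: EEGSynthConfig | None = None) -> FeatureTable:
    """Draw a labeled table of normalized band-power vectors.

    Each pattern is ``baseline + class elevations + N(0, noise_sd)``,
    clipped at zero and normalized to sum to one.  Feature ids are
    ``band00..band31`` in chain order.
    """
    config = config or EEGSynthConfig()
    rng = np.random.default_rng(config.seed)
    base = _baseline(config)
    rows, labels = [], []
    for cls in sorted(config.n_per_class):
        profile = base.copy()
        for (start, stop), elev in config.informative_regions.get(cls, []):
            profile[start:stop] += elev
        n = config.n_per_class[cls]
        block = profile[None, :] + rng.normal(
            0.0, config.noise_sd, size=(n, config.n_features))
        block = np.clip(block, 0.0, None)
        sums = block.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("degenerate all-zero band profile generated")
        rows.append(block / sums[:, None])
        labels.extend([cls] * n)
    values = np.vstack(rows)
    ids = [f"band{b:02d}" for b in range(config.n_features)]
    return FeatureTable(values, np.array(labels), ids)


def _stroke_image(rng: np.random.Generator, n_strokes: int) -> np.ndarray:
    """Random thin line strokes on a 64x64 canvas (class-independent)."""
    img = np.zeros((64, 64), dtype=np.uint8)
    for _ in range(n_strokes):
        r0, c0, r1, c1 = rng.integers(0, 64, size=4)
        rr, cc = line(int(r0), int(c0), int(r1), int(c1))
        img[rr, cc] = 1
        # thicken by one pixel where possible
        rr2 = np.clip(rr + 1, 0, 63)
        img[rr2, cc] = 1
    return img


def generate_char_like_dataset(n_per_class: int = 200,
                               crucial_region: tuple[tuple[int, int],
                                                     tuple[int, int]] = ((1, 4), (10, 14)),
                               seed: int = 0,
                               n_strokes: int = 6) -> FeatureTable:
    """Two classes of stroke images differing only inside a crucial region.

    ``crucial_region`` is ``((row_start, row_stop), (col_start, col_stop))``
    in half-open 16x16 block coordinates (default: a top-right area).  Both
    classes draw strokes from the same distribution; class ``"dog"`` adds a
    dense dot whose pixels are clipped to the crucial region, so outside it
    the class-conditional feature distributions are identical by
    construction.  Features are the 256 block counts; ids ``r00c00`` ..
    ``r15c15`` row-major, matching a 16x16 grid topology.
    """
    (r0, r1), (c0, c1) = crucial_region
    if not (0 <= r0 < r1 <= 16 and 0 <= c0 < c1 <= 16):
        raise ValueError("crucial_region must be a non-empty block range in 16x16")
    rng = np.random.default_rng(seed)
    pr0, pr1, pc0, pc1 = 4 * r0, 4 * r1, 4 * c0, 4 * c1  # pixel bounds
    rows, labels = [], []
    for cls in ("big", "dog"):
        for _ in range(n_per_class):
            img = _stroke_image(rng, n_strokes)
            if cls == "dog":
                cr = rng.uniform(pr0 + 2, pr1 - 2)
                cc_ = rng.uniform(pc0 + 2, pc1 - 2)
                rr, cc2 = disk((cr, cc_), radius=3.0, shape=(64, 64))
                keep = (rr >= pr0) & (rr < pr1) & (cc2 >= pc0) & (cc2 < pc1)
                img[rr[keep], cc2[keep]] = 1
            rows.append(char_subregion_features(img))
            labels.append(cls)
    values = np.asarray(rows, dtype=float)
    ids = [f"r{r:02d}c{c:02d}" for r in range(16) for c in range(16)]
    return FeatureTable(values, np.array(labels), ids)


def crucial_region_indices(crucial_region: tuple[tuple[int, int],
                                                 tuple[int, int]]) -> list[int]:
    """Row-major feature indices of a block region on the 16x16 grid."""
    (r0, r1), (c0, c1) = crucial_region
    return [16 * r + c for r in range(r0, r1) for c in range(c0, c1)]


@dataclass(frozen=True)
class NoiseSpec:
    """The robustness protocol: corrupt ``pattern_fraction`` of the rows in
    ``n_features_modified`` randomly chosen feature cells each."""

    pattern_fraction: float = 0.2
    n_features_modified: int = 6
    mode: Literal["uniform_resample", "permute"] = "uniform_resample"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pattern_fraction <= 1.0:
            raise ValueError("pattern_fraction must be in (0, 1]")
        if self.n_features_modified < 1:
            raise ValueError("n_features_modified must be >= 1")


def inject_noise(table: FeatureTable, spec: NoiseSpec | None = None) -> FeatureTable:
    """Return a copy of the table with noisy patterns injected.

    Exactly ``round(pattern_fraction * n)`` patterns are chosen without
    replacement; in each, ``n_features_modified`` distinct feature cells are
    replaced — by a uniform draw within that feature's observed min-max
    range (``uniform_resample``) or by the value of a random other pattern
    (``permute``).  Labels and all untouched cells are preserved
    bit-exactly.
    """
    spec = spec or NoiseSpec()
    if spec.n_features_modified > table.n_features:
        raise ValueError("n_features_modified exceeds n_features")
    rng = np.random.default_rng(spec.seed)
    values = table.values.copy()
    n = table.n_patterns
    n_noisy = int(np.floor(spec.pattern_fraction * n + 0.5))
    rows = rng.choice(n, size=n_noisy, replace=False)
    col_min = table.values.min(axis=0)
    col_max = table.values.max(axis=0)
    for r in rows:
        feats = rng.choice(table.n_features, size=spec.n_features_modified,
                           replace=False)
        for f in feats:
            old = values[r, f]
            if spec.mode == "uniform_resample":
                if col_max[f] == col_min[f]:
                    continue  # constant feature: no distinct value exists
                new = old
                for _ in range(100):  # ensure the cell actually changes
                    new = rng.uniform(col_min[f], col_max[f])
                    if new != old:
                        break
            elif spec.mode == "permute":
                other = int(rng.integers(0, n - 1))
                if other >= r:
                    other += 1
                new = table.values[other, f]
            else:
                raise ValueError(f"unknown noise mode {spec.mode!r}")
            values[r, f] = new
    return FeatureTable(values, table.labels.copy(), list(table.feature_ids))
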