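"""Application front-ends: spectral band powers and image subregion counts.

The spectral extractor turns a 1-D signal (e.g., an EEG channel) into
per-window feature vectors: the power spectrum of each window is summed
over ``n_bands`` equal-width frequency bands spanning ``(0, f_max]`` and
normalized to sum to one, so the features are relative band powers and are
invariant to signal gain.

The image extractor turns a 64x64 binary image into 256 features: the
foreground-pixel count of each 4x4 block on a 16x16 grid, row-major with
origin at the top-left.  These features take values 0..16 and carry the
2-D grid topology used by the neighborhood search.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np
from scipy.signal import periodogram

__all__ = [
    "SpectralConfig",
    "spectrum_band_features",
    "band_edges",
    "char_subregion_features",
    "load_grid_image",
]


@dataclass(frozen=True)
class SpectralConfig:
    """Windowing and banding for the spectral extractor.

    Defaults follow common rodent-EEG practice: 4-s windows with 1 s of
    shared signal between consecutive windows (hop = 3 s), spectrum summed
    into 32 uniform bands over (0, 50] Hz (width 50/32 = 1.5625 Hz).
    """

    sampling_rate: float
    window_length: float = 4.0
    overlap: float = 1.0
    f_max: float = 50.0
    n_bands: int = 32
    window: str = "boxcar"
    detrend: bool = False

    def __post_init__(self) -> None:
        if self.overlap >= self.window_length:
            raise ValueError("overlap must be shorter than the window")
        if self.n_bands < 1 or self.f_max <= 0:
            raise ValueError("need n_bands >= 1 and f_max > 0")
        n = self.window_length * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "window_length x sampling_rate must be an integer sample count")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_length * self.sampling_rate))

    @property
    def hop_samples(self) -> int:
        return int(round((self.window_length - self.overlap) * self.sampling_rate))

    @property
    def band_width(self) -> float:
        return self.f_max / self.n_bands


def band_edges(config: SpectralConfig) -> np.ndarray:
    """Band boundaries: band ``b`` covers ``(b*df, (b+1)*df]`` with
    ``df = f_max / n_bands``; DC is excluded."""
    return np.arange(config.n_bands + 1) * config.band_width


def spectrum_band_features(signal: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """Normalized band powers per window, shape ``(n_windows, n_bands)``.

    Windows start at multiples of the hop; the final window is truncated at
    the signal end if needed, so every sample belongs to at least one
    window.  Each row sums to 1.
    """
    x = np.asarray(signal, dtype=float).ravel()
    win, hop = config.window_samples, config.hop_samples
    n = len(x)
    if n < win:
        raise ValueError(f"signal ({n} samples) shorter than one window ({win})")
    n_windows = 1 + max(0, ceil((n - win) / hop))
    edges = band_edges(config)
    out = np.empty((n_windows, config.n_bands))
    for w in range(n_windows):
        seg = x[w * hop: w * hop + win]
        freqs, power = periodogram(
            seg, fs=config.sampling_rate, window=config.window,
            detrend=("constant" if config.detrend else False))
        mask = (freqs > 0) & (freqs <= config.f_max)
        # band index for frequency f: smallest b with f <= (b+1)*df
        bands = np.digitize(freqs[mask], edges, right=True) - 1
        sums = np.bincount(bands, weights=power[mask], minlength=config.n_bands)
        total = sums.sum()
        if total <= 0:
            raise ValueError(f"window {w} has zero spectral power in (0, f_max]")
        out[w] = sums / total
    return out


def char_subregion_features(image: np.ndarray) -> np.ndarray:
    """Foreground counts of the 4x4 blocks of a 64x64 binary image.

    Returns a length-256 integer vector in row-major block order; entry
    ``16*r + c`` is the count for block row ``r``, block column ``c``.
    """
    img = np.asarray(image)
    if img.shape != (64, 64):
        raise ValueError(f"expected a 64x64 image, got shape {img.shape}")
    vals = np.unique(img)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("image must be binary (0 = background, 1 = foreground)")
    return img.reshape(16, 4, 16, 4).sum(axis=(1, 3)).astype(int).ravel()


def load_grid_image(path: str | Path) -> np.ndarray:
    """Read a binary image from PGM (P2/P5) or a whitespace 0/1 text grid.

    Any nonzero pixel is treated as foreground.
    """
    path = Path(path)
    head = path.open("rb").read(2)
    if head in (b"P2", b"P5"):
        from PIL import Image

        arr = np.array(Image.open(path))
    else:
        arr = np.loadtxt(path)
    return (arr > 0).astype(np.uint8)
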