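"""Canonical EEG frequency bands and the 1-Hz analysis grid.

The five classical bands used throughout the package are delta (1-4 Hz),
theta (4-8 Hz), alpha (8-13 Hz), beta (13-30 Hz) and gamma (30-49 Hz).
As printed, the band edges overlap; on the integer frequency grid each
boundary bin is assigned to the *lower* band exclusively (half-open
``[fmin, fmax)``), except the top band which keeps its upper edge so that
every grid frequency belongs to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Band", "DEFAULT_BANDS", "default_freqs", "band_bins", "get_band"]


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if not self.fmin < self.fmax:
            raise ValueError(f"band {self.name!r}: fmin must be < fmax")


DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 1.0, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 49.0),
)


def default_freqs() -> np.ndarray:
    """The analysis frequency grid: 1-49 Hz in 1-Hz steps."""
    return np.arange(1.0, 50.0)


def get_band(name: str, bands: tuple[Band, ...] = DEFAULT_BANDS) -> Band:
    for band in bands:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")


def band_bins(band: Band, freqs: np.ndarray, top_inclusive: bool | None = None) -> np.ndarray:
    """Indices into ``freqs`` covered by ``band``.

    Half-open ``[fmin, fmax)``; the band sitting at the top of the grid is
    upper-inclusive (``top_inclusive`` overrides the automatic choice).
    """
    freqs = np.asarray(freqs, dtype=float)
    if top_inclusive is None:
        top_inclusive = band.fmax >= freqs.max() - 1e-9
    mask = (freqs >= band.fmin - 1e-9) & (freqs < band.fmax - 1e-9)
    if top_inclusive:
        mask |= np.isclose(freqs, band.fmax)
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError(f"band {band.name!r} covers no bins of the frequency grid")
    return idx
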