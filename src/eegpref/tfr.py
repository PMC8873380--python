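"""Morlet time-frequency decomposition and the 915 band-power features.

The pipeline's feature set, per epoch:

* 640 power spectral features (PSFs): for each of 128 channels and each of
  the five bands, the relative post-stimulus band-power change
  ``PSF = (V - B) / B``, where ``V`` is the time-frequency power averaged
  over the photograph-viewing window (0-2 s) and the band's frequency
  bins, and ``B`` the same average over the pre-stimulus baseline
  (-0.2-0 s). ``V`` and ``B`` are two-stage means — first over the band's
  frequency bins, then over the window's grid times.
* 275 asymmetry scores (ASs): for each of the 55 left/right symmetric
  electrode pairs and each band, ``AS = PSF(left) - PSF(right)`` (a raw
  band-power difference ``V(left) - V(right)`` is available as an option).

Power comes from convolving each channel with five-cycle complex Morlet
wavelets at integer frequencies 1-49 Hz and squaring the magnitude; the
time-frequency plane is sampled on a nominal 12-ms hop grid anchored at
stimulus onset (each grid time evaluated at the nearest sample).

Edge handling: a five-cycle wavelet at 1 Hz is far longer than the 2.2-s
epoch, so low-frequency cells are computed by zero-padded convolution and
flagged by a per-cell validity mask (full wavelet support inside the
epoch). Band averages use valid cells only; for frequencies with no valid
cell in the requested window (unavoidable for low frequencies in the
0.2-s baseline) the average falls back to all cells of that frequency
unless ``strict=True``, in which case an error is raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from sklearn.base import BaseEstimator, TransformerMixin

from .bands import Band, DEFAULT_BANDS, band_bins, default_freqs, get_band
from .epochs import EpochSet, Montage

__all__ = [
    "TFR",
    "PV_WINDOW",
    "BS_WINDOW",
    "morlet_wavelet",
    "morlet_tfr",
    "band_time_average",
    "psf",
    "asymmetry_scores",
    "MorletFeatureExtractor",
    "extract_features",
    "feature_name",
    "parse_feature_name",
]

HOP = 0.012  # nominal time-grid increment, seconds
PV_WINDOW = (0.0, 2.0)  # photograph-viewing window (half-open, onset included)
BS_WINDOW = (-0.2, 0.0)  # baseline window (half-open, onset excluded)


@dataclass
class TFR:
    """Per-epoch time-frequency power on the 1-Hz x 12-ms grid.

    ``valid[f, t]`` marks cells whose wavelet support lies fully inside
    the epoch; invalid cells hold zero-padded (edge-attenuated) power.
    """

    power: np.ndarray  # (n_channels, n_freqs, n_times), >= 0
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray  # (n_freqs, n_times) bool
    epoch_index: int = 0

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("power must be (channels, freqs, times)")
        if self.power.shape[1:] != (self.freqs.size, self.times.size):
            raise ValueError("power shape inconsistent with freqs/times")
        if self.valid.shape != (self.freqs.size, self.times.size):
            raise ValueError("valid mask shape inconsistent")


def morlet_wavelet(freq: float, sfreq: float, n_cycles: float = 5.0) -> np.ndarray:
    """Unit-energy complex Morlet wavelet (support +-5 sigma_t)."""
    if freq <= 0:
        raise ValueError("freq must be positive")
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(round(5.0 * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2) / sfreq)
    return w


def _grid(times: np.ndarray, hop: float) -> tuple[np.ndarray, np.ndarray]:
    """Nominal hop grid anchored at t=0, mapped to nearest sample indices."""
    kmin = int(np.ceil(times[0] / hop - 1e-9))
    kmax = int(np.floor(times[-1] / hop + 1e-9))
    grid_times = hop * np.arange(kmin, kmax + 1)
    sfreq = 1.0 / (times[1] - times[0])
    idx = np.round((grid_times - times[0]) * sfreq).astype(int)
    return grid_times, idx


def _validity(wavelet_lengths: Sequence[int], sample_idx: np.ndarray, n_samples: int) -> np.ndarray:
    valid = np.zeros((len(wavelet_lengths), sample_idx.size), dtype=bool)
    for k, L in enumerate(wavelet_lengths):
        half = (L - 1) // 2
        valid[k] = (sample_idx - half >= 0) & (sample_idx + half <= n_samples - 1)
    return valid


def _morlet_power(
    data: np.ndarray,
    sfreq: float,
    freqs: np.ndarray,
    n_cycles: float,
    sample_idx: np.ndarray,
) -> tuple[np.ndarray, list[int]]:
    """Squared-magnitude Morlet coefficients of ``data`` at grid samples.

    ``data`` is (epochs, channels, samples); returns
    (epochs, channels, freqs, grid) power plus the wavelet lengths.
    Convolution is zero-padded FFT convolution with 'same' alignment;
    signal FFTs are shared across frequencies of equal padded length.
    """
    n = data.shape[-1]
    wavelets = [morlet_wavelet(f, sfreq, n_cycles) for f in freqs]
    lengths = [w.size for w in wavelets]
    if min(lengths) > n:
        raise ValueError(
            "epoch shorter than one wavelet at the highest analysis frequency"
        )
    nffts = np.array([next_fast_len(n + L - 1) for L in lengths])
    out = np.empty(data.shape[:-1] + (len(wavelets), sample_idx.size))
    for nfft in np.unique(nffts):
        data_f = fft(data, nfft, axis=-1)
        for k in np.nonzero(nffts == nfft)[0]:
            w_f = fft(wavelets[k], nfft)
            y = ifft(data_f * w_f, axis=-1)
            cols = (lengths[k] - 1) // 2 + sample_idx  # 'same' alignment
            seg = y[..., cols]
            out[..., k, :] = seg.real**2 + seg.imag**2
    return out, lengths


def morlet_tfr(
    epoch_set: EpochSet,
    n_cycles: float = 5.0,
    freqs: np.ndarray | None = None,
    hop: float = HOP,
    batch_size: int = 8,
) -> list[TFR]:
    """Time-frequency decomposition of every epoch.

    Returns one :class:`TFR` per epoch with power on the 1-49 Hz x 12-ms
    grid and the shared validity mask.
    """
    if freqs is None:
        freqs = default_freqs()
    freqs = np.asarray(freqs, dtype=float)
    times = epoch_set.times
    grid_times, sample_idx = _grid(times, hop)
    out: list[TFR] = []
    valid = None
    for start in range(0, epoch_set.n_epochs, batch_size):
        stop = min(start + batch_size, epoch_set.n_epochs)
        power, lengths = _morlet_power(
            np.asarray(epoch_set.data[start:stop], dtype=float),
            epoch_set.sfreq, freqs, n_cycles, sample_idx,
        )
        if valid is None:
            valid = _validity(lengths, sample_idx, epoch_set.n_samples)
        for j in range(start, stop):
            out.append(
                TFR(power=power[j - start], freqs=freqs, times=grid_times,
                    valid=valid, epoch_index=j)
            )
    return out


def _band_window_weights(
    freqs: np.ndarray,
    times: np.ndarray,
    valid: np.ndarray,
    band: Band,
    window: tuple[float, float],
    strict: bool = False,
) -> np.ndarray:
    """Cell weights realizing the two-stage band/window mean.

    Weight ``1 / (n_bins * n_times_f)`` on the contributing cells of each
    band frequency, where ``n_times_f`` counts that frequency's valid grid
    times inside the half-open window (all window times if none is valid
    and ``strict`` is off).
    """
    bins = band_bins(band, freqs)
    tsel = (times >= window[0] - 1e-12) & (times < window[1] - 1e-12)
    if not tsel.any():
        raise ValueError(f"window {window} contains no grid time points")
    weights = np.zeros((freqs.size, times.size))
    for f in bins:
        cols = valid[f] & tsel
        if not cols.any():
            if strict:
                raise ValueError(
                    f"no valid time-frequency cells for {band.name} at {freqs[f]:g} Hz "
                    f"in window {window} (wavelet support exceeds the epoch)"
                )
            cols = tsel
        weights[f, cols] = 1.0 / (bins.size * cols.sum())
    return weights


def band_time_average(
    tfr: TFR,
    band: Band | str,
    window: tuple[float, float],
    strict: bool = False,
) -> np.ndarray:
    """Mean power over a band's frequency bins then the window's times.

    Returns one value per channel. Only valid cells contribute; see the
    module docstring for the low-frequency fallback and ``strict``.
    """
    if isinstance(band, str):
        band = get_band(band)
    weights = _band_window_weights(tfr.freqs, tfr.times, tfr.valid, band, window, strict)
    return np.tensordot(tfr.power, weights, axes=([1, 2], [0, 1]))


def psf(v: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Relative band-power change from baseline, ``(V - B) / B``."""
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr <= 0):
        raise ValueError("baseline band power must be positive")
    return (np.asarray(v, dtype=float) - b_arr) / b_arr


def asymmetry_scores(
    psf_by_channel: "pd.DataFrame | dict",
    montage: Montage,
) -> pd.DataFrame:
    """Left-minus-right difference for every montage pair.

    ``psf_by_channel`` maps channel name -> per-band values (a DataFrame
    with channels as columns, or a plain mapping of vectors/scalars).
    """
    table = pd.DataFrame(psf_by_channel)
    missing = [ch for pair in montage.pairs for ch in pair if ch not in table.columns]
    if missing:
        raise ValueError(f"pair members missing from PSF table: {sorted(set(missing))}")
    out = {}
    for left, right in montage.pairs:
        out[f"{left}/{right}"] = table[left] - table[right]
    return pd.DataFrame(out, index=table.index)


def feature_name(kind: str, band: str, where: str | tuple[str, str]) -> str:
    if isinstance(where, tuple):
        where = f"{where[0]}/{where[1]}"
    return f"{kind}|{band}|{where}"


def parse_feature_name(name: str) -> tuple[str, str, str | tuple[str, str]]:
    """Invert :func:`feature_name`: -> (kind, band, channel or (left, right))."""
    kind, band, where = name.split("|")
    if kind == "AS":
        left, right = where.split("/")
        return kind, band, (left, right)
    return kind, band, where


class MorletFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping an :class:`EpochSet` to the band-power feature table.

    ``transform`` returns a DataFrame with ``5 * n_channels`` PSF columns
    followed by ``5 * n_pairs`` asymmetry columns (band-major order), with
    self-describing names like ``PSF|alpha|L03`` and ``AS|alpha|L03/R03``.

    Parameters
    ----------
    montage : Montage
        Channel names and symmetric pairs; must match the epochs.
    bands : tuple of Band
        Frequency bands (default: the five classical bands).
    n_cycles : float
        Morlet wavelet width in cycles (default 5).
    hop : float
        Nominal time-grid increment in seconds (default 0.012).
    pv_window, bs_window : (float, float)
        Post-stimulus and baseline averaging windows, half-open.
    asymmetry : {"psf", "power"}
        Whether asymmetry scores subtract baseline-corrected PSFs
        (default) or raw viewing-window band powers.
    strict : bool
        Error on frequencies without fully supported wavelet cells
        instead of falling back to zero-padded cells.
    """

    def __init__(
        self,
        montage: Montage,
        bands: tuple[Band, ...] = DEFAULT_BANDS,
        n_cycles: float = 5.0,
        hop: float = HOP,
        pv_window: tuple[float, float] = PV_WINDOW,
        bs_window: tuple[float, float] = BS_WINDOW,
        asymmetry: str = "psf",
        strict: bool = False,
        batch_size: int = 8,
    ) -> None:
        self.montage = montage
        self.bands = bands
        self.n_cycles = n_cycles
        self.hop = hop
        self.pv_window = pv_window
        self.bs_window = bs_window
        self.asymmetry = asymmetry
        self.strict = strict
        self.batch_size = batch_size

    def fit(self, X: EpochSet, y=None) -> "MorletFeatureExtractor":
        if not isinstance(X, EpochSet):
            raise TypeError("X must be an EpochSet")
        if tuple(X.channel_names) != tuple(self.montage.channel_names):
            raise ValueError("epoch channels do not match the montage")
        if self.asymmetry not in ("psf", "power"):
            raise ValueError("asymmetry must be 'psf' or 'power'")
        self.feature_names_out_ = self._column_names()
        self.n_features_out_ = len(self.feature_names_out_)
        return self

    def _column_names(self) -> list[str]:
        cols = [
            feature_name("PSF", band.name, ch)
            for band in self.bands
            for ch in self.montage.channel_names
        ]
        cols += [
            feature_name("AS", band.name, pair)
            for band in self.bands
            for pair in self.montage.pairs
        ]
        return cols

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self.feature_names_out_, dtype=object)

    def transform(self, X: EpochSet) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "feature_names_out_")
        if tuple(X.channel_names) != tuple(self.montage.channel_names):
            raise ValueError("epoch channels do not match the montage")
        freqs = default_freqs()
        grid_times, sample_idx = _grid(X.times, self.hop)

        n_ch = X.n_channels
        n_bands = len(self.bands)
        v_mat = np.empty((X.n_epochs, n_bands, n_ch))
        b_mat = np.empty_like(v_mat)
        weights = None
        for start in range(0, X.n_epochs, self.batch_size):
            stop = min(start + self.batch_size, X.n_epochs)
            power, lengths = _morlet_power(
                np.asarray(X.data[start:stop], dtype=float),
                X.sfreq, freqs, self.n_cycles, sample_idx,
            )
            if weights is None:
                valid = _validity(lengths, sample_idx, X.n_samples)
                weights = [
                    (
                        _band_window_weights(freqs, grid_times, valid, band,
                                             self.pv_window, self.strict),
                        _band_window_weights(freqs, grid_times, valid, band,
                                             self.bs_window, self.strict),
                    )
                    for band in self.bands
                ]
            for bi, (wv, wb) in enumerate(weights):
                v_mat[start:stop, bi] = np.tensordot(power, wv, axes=([2, 3], [0, 1]))
                b_mat[start:stop, bi] = np.tensordot(power, wb, axes=([2, 3], [0, 1]))

        psf_mat = psf(v_mat, b_mat)  # (epochs, bands, channels)
        ch_index = {ch: i for i, ch in enumerate(self.montage.channel_names)}
        left_idx = [ch_index[l] for l, _ in self.montage.pairs]
        right_idx = [ch_index[r] for _, r in self.montage.pairs]
        source = psf_mat if self.asymmetry == "psf" else v_mat
        as_mat = source[:, :, left_idx] - source[:, :, right_idx]

        blocks = [psf_mat.reshape(X.n_epochs, -1), as_mat.reshape(X.n_epochs, -1)]
        return pd.DataFrame(
            np.concatenate(blocks, axis=1), columns=self.feature_names_out_
        )


def extract_features(
    epoch_set: EpochSet, montage: Montage, **kwargs
) -> pd.DataFrame:
    """One-shot feature extraction; see :class:`MorletFeatureExtractor`."""
    extractor = MorletFeatureExtractor(montage=montage, **kwargs)
    return extractor.fit(epoch_set).transform(epoch_set)
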