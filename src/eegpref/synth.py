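"""Synthetic epoched EEG with the statistical structure the pipeline assumes.

Real recordings of the dating-platform task are not publicly deposited, so
this module simulates epochs that carry exactly the signal structure the
feature-extraction and classification stages are designed to detect:

* a 1/f ("pink") background on every channel,
* band-limited oscillations (constant-amplitude sinusoids with random
  frequency within the band and random phase per epoch) on the channels
  named in the effect specification,
* class-conditional power changes: for epochs of the ``engendered`` class
  the post-onset (t >= 0) oscillation amplitude is multiplied by the
  configured factor while the pre-onset baseline is untouched — the
  event-related (de)synchronization the relative band-power feature
  (V - B)/B is built to measure,
* hemispheric asymmetry effects: a pair effect applies the multiplier to
  the left member and its reciprocal to the right member, giving the
  asymmetry score a controllable sign and magnitude,
* rating metadata that follows the true class (engendered -> 2 or 3,
  un-engendered -> 0) with configurable label noise and a fraction of
  ambiguous rating-1 trials that downstream labeling excludes.

A per-subject random effect scales the (log) effect multiplier so that
subject-wise cross-validation sees realistic between-subject variability.
The montage is positionless bookkeeping: left channels ``L01..``, right
channels ``R01..`` (paired by index) and unpaired ``M..`` channels,
BioSemi-like only in its 128-channel / 55-pair geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet, Montage

__all__ = [
    "RatingRecord",
    "EffectSpec",
    "SynthConfig",
    "generate_montage",
    "generate_dataset",
    "demo_effects",
    "demo_config",
]

N_PAIRS = 55  # symmetric electrode pairs on the standard 128-channel cap

_EPOCH_CHUNK = 32  # epochs generated per noise chunk (memory bound, fixed for determinism)


@dataclass(frozen=True)
class RatingRecord:
    """Self-report metadata for one trial."""

    subject_id: str
    trial_id: int
    ira_rating: int  # 0-3 "would you date this person?"
    acquaintance_rating: int  # 0-2 "have you seen this person before?"
    true_class: str  # generative ground truth: engendered / un-engendered

    def __post_init__(self) -> None:
        if self.ira_rating not in (0, 1, 2, 3):
            raise ValueError("ira_rating must be in 0..3")
        if self.acquaintance_rating not in (0, 1, 2):
            raise ValueError("acquaintance_rating must be in 0..2")


@dataclass(frozen=True)
class EffectSpec:
    """A class-conditional band-power effect.

    ``channels`` receive the multiplier directly (bilateral power change);
    each (left, right) entry of ``pairs`` receives the multiplier on the
    left member and its reciprocal on the right (asymmetry). A multiplier
    of 1.0 is a null effect.
    """

    band: str
    multiplier: float
    channels: tuple[str, ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if not self.channels and not self.pairs:
            raise ValueError("effect must reference at least one channel or pair")


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the recording setup being emulated."""

    n_subjects: int = 10
    trials_per_subject: int = 60
    sfreq: float = 512.0
    epoch_window: tuple[float, float] = (-0.2, 2.0)
    n_channels: int = 128
    effects: tuple[EffectSpec, ...] = ()
    noise_exponent: float = 1.0  # 1/f^a amplitude-spectrum slope of the background
    snr: float = 1.0  # oscillation RMS relative to background RMS
    rating_noise: float = 0.05  # probability a rating contradicts the true class
    rating1_fraction: float = 0.07  # ambiguous trials later excluded by labeling
    engendered_prevalence: float = 0.086  # ~1:10.6 class imbalance
    subject_sigma: float = 0.1  # SD of the per-subject effect-size random effect
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValueError("n_subjects and trials_per_subject must be positive")
        if not 0 <= self.rating_noise < 0.5:
            raise ValueError("rating_noise must be in [0, 0.5)")
        if not 0 <= self.rating1_fraction < 1:
            raise ValueError("rating1_fraction must be in [0, 1)")
        if not 0 < self.engendered_prevalence < 1:
            raise ValueError("engendered_prevalence must be in (0, 1)")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be increasing")
        if self.sfreq <= 0 or self.snr < 0 or self.subject_sigma < 0:
            raise ValueError("sfreq must be positive; snr and subject_sigma non-negative")


def generate_montage(n_channels: int = 128, n_pairs: int = N_PAIRS) -> Montage:
    """Deterministic symmetric-pair montage: 55 (L, R) pairs + unpaired channels.

    Channel order is L01, R01, L02, R02, ..., then midline/unpaired M01...
    Raises if ``n_channels`` cannot host the 55 pairs.
    """
    if n_channels < 2 * n_pairs:
        raise ValueError(
            f"need at least {2 * n_pairs} channels for {n_pairs} symmetric pairs, got {n_channels}"
        )
    pairs = tuple((f"L{i:02d}", f"R{i:02d}") for i in range(1, n_pairs + 1))
    names: list[str] = []
    for left, right in pairs:
        names.extend((left, right))
    midline = tuple(f"M{i:02d}" for i in range(1, n_channels - 2 * n_pairs + 1))
    names.extend(midline)
    return Montage(channel_names=tuple(names), pairs=pairs, midline=midline)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                sfreq: float, exponent: float) -> np.ndarray:
    """1/f^exponent (amplitude) noise, unit RMS per trace."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def _resolve_effect_channels(effect: EffectSpec, montage: Montage) -> list[tuple[str, int]]:
    """(channel, role) list for one effect; role +1 = multiplier, -1 = reciprocal."""
    known = set(montage.channel_names)
    pair_set = set(montage.pairs)
    out: list[tuple[str, int]] = []
    for ch in effect.channels:
        if ch not in known:
            raise ValueError(f"effect channel {ch!r} not in montage")
        out.append((ch, +1))
    for left, right in effect.pairs:
        if (left, right) not in pair_set:
            raise ValueError(f"effect pair ({left}, {right}) not a montage pair")
        out.append((left, +1))
        out.append((right, -1))
    return out


def generate_dataset(
    config: SynthConfig, montage: Montage | None = None,
) -> tuple[EpochSet, list[RatingRecord]]:
    """Simulate epoched EEG plus per-trial rating metadata.

    Identical config (including seed) yields bit-identical output. The
    returned :class:`EpochSet` is unlabeled; apply
    :func:`eegpref.epochs.label_epochs` to the rating records.
    """
    from . import bands as _bands

    if montage is None:
        montage = generate_montage(config.n_channels)
    elif montage.n_channels != config.n_channels:
        raise ValueError("montage channel count does not match config.n_channels")

    band_by_name = {b.name: b for b in _bands.DEFAULT_BANDS}
    resolved = []
    for eff in config.effects:
        if eff.band not in band_by_name:
            raise ValueError(f"unknown band {eff.band!r} in effect spec")
        resolved.append((eff, band_by_name[eff.band], _resolve_effect_channels(eff, montage)))

    rng = np.random.default_rng(config.seed)
    n_ep = config.n_subjects * config.trials_per_subject
    t0, t1 = config.epoch_window
    n = int(round(config.sfreq * (t1 - t0)))
    times = t0 + np.arange(n) / config.sfreq
    post = times >= 0

    subject_ids = np.array(
        [f"S{s:02d}" for s in range(config.n_subjects) for _ in range(config.trials_per_subject)],
        dtype=object,
    )
    subject_index = np.repeat(np.arange(config.n_subjects), config.trials_per_subject)

    # --- trial classes and ratings -------------------------------------
    engendered = rng.random(n_ep) < config.engendered_prevalence
    high = rng.integers(2, 4, size=n_ep)  # 2 or 3, equiprobable
    flip = rng.random(n_ep) < config.rating_noise
    ira = np.where(engendered, high, 0)
    ira[flip & engendered] = 0
    ira[flip & ~engendered] = high[flip & ~engendered]
    ambiguous = rng.random(n_ep) < config.rating1_fraction
    ira[ambiguous] = 1
    acq = rng.choice([0, 1, 2], size=n_ep, p=[0.9, 0.07, 0.03])

    # per-subject random effect on log effect size (one draw per subject x effect)
    gamma = rng.normal(1.0, config.subject_sigma, size=(config.n_subjects, max(len(resolved), 1)))

    # --- signal --------------------------------------------------------
    data = np.zeros((n_ep, montage.n_channels, n), dtype=np.float32)
    for start in range(0, n_ep, _EPOCH_CHUNK):
        stop = min(start + _EPOCH_CHUNK, n_ep)
        data[start:stop] = _pink_noise(
            rng, (stop - start, montage.n_channels), n, config.sfreq, config.noise_exponent
        )

    ch_index = {ch: i for i, ch in enumerate(montage.channel_names)}
    amp = config.snr * np.sqrt(2.0)  # sinusoid amplitude for unit-RMS oscillation
    for k, (eff, band, members) in enumerate(resolved):
        for ch, role in members:
            freq = rng.uniform(band.fmin, band.fmax, size=n_ep)
            phase = rng.uniform(0.0, 2 * np.pi, size=n_ep)
            osc = amp * np.sin(2 * np.pi * freq[:, None] * times[None, :] + phase[:, None])
            m = eff.multiplier ** (gamma[subject_index, k] * role)
            gate = np.ones(n_ep)
            gate[engendered] = m[engendered]
            osc[:, post] *= gate[:, None]
            data[:, ch_index[ch], :] += osc.astype(np.float32)

    epoch_set = EpochSet(
        data=data,
        sfreq=config.sfreq,
        t0_offset=t0,
        channel_names=montage.channel_names,
        subject_ids=subject_ids,
    )
    records = [
        RatingRecord(
            subject_id=str(subject_ids[j]),
            trial_id=j,
            ira_rating=int(ira[j]),
            acquaintance_rating=int(acq[j]),
            true_class="engendered" if engendered[j] else "un-engendered",
        )
        for j in range(n_ep)
    ]
    return epoch_set, records


def demo_effects(montage: Montage) -> tuple[EffectSpec, ...]:
    """Strong, physiologically styled effect set used by the demo pipeline.

    Bilateral alpha/beta suppression on a few "posterior" channels
    (event-related desynchronization) plus alpha and theta asymmetries on
    a few pairs — the pattern the attraction-decoding literature reports.
    """
    p = montage.pairs
    return (
        EffectSpec(band="alpha", multiplier=0.5,
                   channels=(p[49][0], p[49][1], montage.midline[0] if montage.midline else p[48][0])),
        EffectSpec(band="beta", multiplier=0.6, channels=(p[47][0], p[47][1])),
        EffectSpec(band="alpha", multiplier=1.6, pairs=(p[0], p[1], p[2])),
        EffectSpec(band="theta", multiplier=1.4, pairs=(p[9],)),
    )


def demo_config(seed: int = 0, n_subjects: int = 10, trials_per_subject: int = 60,
                null: bool = False) -> SynthConfig:
    """Separable study conditions: strong effects, ratings faithful to class.

    Rating noise is off here because, at the ~1:10 class imbalance, even a
    small flip rate floods the minority class with effect-free epochs and
    the run then measures label contamination rather than decodability.
    With ``null=True`` every effect multiplier is set to 1.0, leaving the
    oscillations in place but class-independent — the matched null
    condition.
    """
    montage = generate_montage(128)
    effects = demo_effects(montage)
    if null:
        effects = tuple(
            EffectSpec(band=e.band, multiplier=1.0, channels=e.channels, pairs=e.pairs)
            for e in effects
        )
    return SynthConfig(
        n_subjects=n_subjects,
        trials_per_subject=trials_per_subject,
        effects=effects,
        snr=1.0,
        rating_noise=0.0,
        seed=seed,
    )
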