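"""Epoched EEG container, rating-based labeling, class balancing and file I/O.

An :class:`EpochSet` holds a stack of fixed-length multi-channel EEG epochs
cut around stimulus onset (by default -0.2 s to +2.0 s, half-open, at
512 Hz -> 1126 samples) together with per-epoch metadata: the recorded
subject and a class label derived from the self-reported romantic-interest
rating. A :class:`Montage` records the channel names plus the left/right
symmetric electrode pairs used for the hemispheric-asymmetry features.

Labeling rule (from the 0-3 "would you date this person?" scale):
ratings 2 and 3 -> ``engendered``, 0 -> ``un-engendered``, and the
ambiguous rating 1 -> ``excluded``. Because attraction is rare, the
``un-engendered`` class vastly outnumbers the ``engendered`` one;
:func:`balance_classes` subsamples the majority class (uniform, without
replacement, seed-reproducible) so both classes match the minority count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LABEL_ENGENDERED",
    "LABEL_UNENGENDERED",
    "LABEL_EXCLUDED",
    "LABEL_UNLABELED",
    "Montage",
    "EpochSet",
    "label_epochs",
    "balance_classes",
    "average_reference",
    "write_epochs",
    "read_epochs",
]

LABEL_ENGENDERED = "engendered"
LABEL_UNENGENDERED = "un-engendered"
LABEL_EXCLUDED = "excluded"
LABEL_UNLABELED = "unlabeled"
_KNOWN_LABELS = (LABEL_ENGENDERED, LABEL_UNENGENDERED, LABEL_EXCLUDED, LABEL_UNLABELED)


@dataclass(frozen=True)
class Montage:
    """Channel names plus left/right symmetric pairs and midline channels."""

    channel_names: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        names = set(self.channel_names)
        if len(names) != len(self.channel_names):
            raise ValueError("duplicate channel names in montage")
        seen: set[str] = set()
        for left, right in self.pairs:
            if left == right:
                raise ValueError(f"pair ({left}, {right}) has identical members")
            for ch in (left, right):
                if ch not in names:
                    raise ValueError(f"pair member {ch!r} not among montage channels")
                if ch in seen:
                    raise ValueError(f"channel {ch!r} appears in more than one pair")
                seen.add(ch)
        for ch in self.midline:
            if ch not in names:
                raise ValueError(f"midline channel {ch!r} not among montage channels")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channel_names": list(self.channel_names),
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        payload = json.loads(Path(path).read_text())
        return cls(
            channel_names=tuple(payload["channel_names"]),
            pairs=tuple((p[0], p[1]) for p in payload["pairs"]),
            midline=tuple(payload.get("midline", ())),
        )


@dataclass
class EpochSet:
    """Epochs x channels x samples EEG array with time axis and metadata.

    ``t0_offset`` is the time of the first sample relative to stimulus
    onset (seconds, negative = pre-stimulus). The epoch window is treated
    as half-open, so the default -0.2..2.0 s span at 512 Hz holds
    ``round(512 * 2.2) = 1126`` samples and no sample falls exactly on
    onset (baseline samples satisfy ``t < 0``).
    """

    data: np.ndarray
    sfreq: float
    channel_names: tuple[str, ...]
    t0_offset: float = -0.2
    subject_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel_names length does not match data")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        n = self.n_epochs
        if self.subject_ids is None:
            self.subject_ids = np.array(["S00"] * n, dtype=object)
        else:
            self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.labels is None:
            self.labels = np.array([LABEL_UNLABELED] * n, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        for arr, what in ((self.subject_ids, "subject_ids"), (self.labels, "labels")):
            if arr.shape != (n,):
                raise ValueError(f"{what} must have one entry per epoch")
        bad = set(self.labels) - set(_KNOWN_LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample times relative to stimulus onset (seconds)."""
        return self.t0_offset + np.arange(self.n_samples) / self.sfreq

    def select(self, indices: Sequence[int] | np.ndarray) -> "EpochSet":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            data=self.data[idx],
            subject_ids=self.subject_ids[idx].copy(),
            labels=self.labels[idx].copy(),
        )


def label_epochs(ratings: Iterable) -> np.ndarray:
    """Map per-epoch romantic-interest ratings to class labels.

    Accepts either integers 0-3 or objects with an ``ira_rating``
    attribute (e.g. :class:`~eegpref.synth.RatingRecord`). Ratings 2/3 ->
    engendered, 0 -> un-engendered, 1 -> excluded; anything else raises.
    """
    out = []
    for r in ratings:
        value = getattr(r, "ira_rating", r)
        value = int(value)
        if value in (2, 3):
            out.append(LABEL_ENGENDERED)
        elif value == 0:
            out.append(LABEL_UNENGENDERED)
        elif value == 1:
            out.append(LABEL_EXCLUDED)
        else:
            raise ValueError(f"rating {value} outside the 0-3 scale")
    return np.array(out, dtype=object)


def balance_classes(epoch_set: EpochSet, seed: int) -> EpochSet:
    """Equalize class counts by subsampling the majority class.

    Keeps every epoch of the minority class, draws the same number from
    the majority class uniformly without replacement, drops excluded and
    unlabeled epochs, and preserves the original epoch order.
    """
    labels = epoch_set.labels
    eng = np.nonzero(labels == LABEL_ENGENDERED)[0]
    une = np.nonzero(labels == LABEL_UNENGENDERED)[0]
    if eng.size == 0 or une.size == 0:
        raise ValueError(
            f"both classes must be non-empty (engendered={eng.size}, un-engendered={une.size})"
        )
    minority, majority = (eng, une) if eng.size <= une.size else (une, eng)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    idx = np.sort(np.concatenate([minority, kept_majority]))
    return epoch_set.select(idx)


def average_reference(epoch_set: EpochSet) -> EpochSet:
    """Subtract the per-sample mean across channels (off by default upstream)."""
    data = epoch_set.data - epoch_set.data.mean(axis=1, keepdims=True)
    return replace(epoch_set, data=data)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_epochs(epoch_set: EpochSet, path: str | Path) -> None:
    """Write epochs as ``<path>.npz`` (array) + ``<path>.json`` (metadata)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    np.savez_compressed(path, data=epoch_set.data)
    meta = {
        "sfreq": epoch_set.sfreq,
        "t0_offset": epoch_set.t0_offset,
        "channel_names": list(epoch_set.channel_names),
        "subject_ids": [str(s) for s in epoch_set.subject_ids],
        "labels": [str(l) for l in epoch_set.labels],
        "n_epochs": int(epoch_set.n_epochs),
        "n_samples": int(epoch_set.n_samples),
    }
    _sidecar_path(path).write_text(json.dumps(meta))


def read_epochs(path: str | Path) -> EpochSet:
    """Read an epoch container written by :func:`write_epochs`.

    Raises a descriptive error on a missing sidecar, a truncated or
    corrupt array file, or metadata that does not match the array shape.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(f"epoch array file not found: {path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar}")
    try:
        with np.load(path) as npz:
            data = npz["data"]
    except Exception as exc:  # zipfile/pickle errors for truncated files
        raise IOError(f"corrupt or truncated epoch container {path}: {exc}") from exc
    meta = json.loads(sidecar.read_text())
    if data.shape[0] != meta["n_epochs"] or data.shape[2] != meta["n_samples"]:
        raise IOError(f"metadata/array shape mismatch in {path}")
    return EpochSet(
        data=data,
        sfreq=float(meta["sfreq"]),
        t0_offset=float(meta["t0_offset"]),
        channel_names=tuple(meta["channel_names"]),
        subject_ids=np.array(meta["subject_ids"], dtype=object),
        labels=np.array(meta["labels"], dtype=object),
    )
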