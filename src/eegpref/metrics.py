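"""Confusion-matrix metrics, the polygon-area metric, and CV aggregation.

With the ``engendered`` class as positive, the six base metrics are

    CA = (TP + TN) / (TP + TN + FP + FN)      classification accuracy
    SE = TP / (TP + FN)                        sensitivity (recall)
    SP = TN / (TN + FP)                        specificity
    JI = TP / (TP + FP + FN)                   Jaccard index
    FM = 2 TP / (2 TP + FP + FN)               F-measure
    AUC                                        area under the ROC curve

The polygon area metric (PAM) summarizes the six: place them as radii of
a hexagon at 60-degree spacing in the order (CA, SE, SP, AUC, JI, FM) and
divide the hexagon's area by that of the regular unit hexagon:

    PAM = sum_k r_k r_{k+1} sin60 / 2  /  (6 sin60 / 2)
        = (1/6) sum_k r_k r_{k+1},    r_7 = r_1.

All metrics live in [0, 1]; algebraically FM >= JI always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .epochs import LABEL_ENGENDERED, LABEL_UNENGENDERED

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "basic_metrics",
    "auc",
    "pam",
    "aggregate",
]

_METRIC_ORDER = ("ca", "se", "sp", "auc", "ji", "fm", "pam")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive class = engendered."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    positive: str = LABEL_ENGENDERED,
    negative: str = LABEL_UNENGENDERED,
) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from two equal-length label vectors."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    allowed = {positive, negative}
    bad = (set(t) | set(p)) - allowed
    if bad:
        raise ValueError(f"labels outside {sorted(allowed)}: {sorted(map(str, bad))}")
    return ConfusionMatrix(
        tp=int(np.sum((t == positive) & (p == positive))),
        fp=int(np.sum((t == negative) & (p == positive))),
        fn=int(np.sum((t == positive) & (p == negative))),
        tn=int(np.sum((t == negative) & (p == negative))),
    )


def _ratio(num: int, den: int, metric: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"{metric} undefined: denominator is zero")
    return num / den


def basic_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """CA, SE, SP, JI and FM from the counts."""
    if cm.total == 0:
        raise ZeroDivisionError("metrics undefined for an empty confusion matrix")
    return {
        "ca": _ratio(cm.tp + cm.tn, cm.total, "CA"),
        "se": _ratio(cm.tp, cm.tp + cm.fn, "SE"),
        "sp": _ratio(cm.tn, cm.tn + cm.fp, "SP"),
        "ji": _ratio(cm.tp, cm.tp + cm.fp + cm.fn, "JI"),
        "fm": _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "FM"),
    }


def auc(scores: Sequence[float], true_labels: Sequence) -> float:
    """Area under the ROC curve (rank / Mann-Whitney formulation).

    ``true_labels`` may be 0/1 or the two class-name strings; ``scores``
    are continuous positive-class decision values.
    """
    y = np.asarray(true_labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = (np.asarray(true_labels, dtype=object) == LABEL_ENGENDERED).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined: the truth vector contains a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def pam(ca: float, se: float, sp: float, auc: float, ji: float, fm: float) -> float:
    """Polygon (hexagon) area metric over the six base metrics.

    Vertex order (CA, SE, SP, AUC, JI, FM); the sin(60) factors of the
    triangle areas cancel against the unit-hexagon normalization.
    """
    r = np.array([ca, se, sp, auc, ji, fm], dtype=float)
    if np.any(r < 0) or np.any(r > 1) or np.any(~np.isfinite(r)):
        raise ValueError("all six metrics must lie in [0, 1]")
    return float(np.sum(r * np.roll(r, -1)) / 6.0)


@dataclass(frozen=True)
class MetricsReport:
    """The seven metrics of one evaluation."""

    ca: float
    se: float
    sp: float
    auc: float
    ji: float
    fm: float
    pam: float

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix, auc_value: float) -> "MetricsReport":
        base = basic_metrics(cm)
        if np.isnan(auc_value):
            pam_value = float("nan")
        else:
            pam_value = pam(base["ca"], base["se"], base["sp"], auc_value,
                            base["ji"], base["fm"])
        return cls(auc=float(auc_value), pam=pam_value, **base)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in _METRIC_ORDER}


def aggregate(reports: Iterable[MetricsReport]) -> pd.DataFrame:
    """Unweighted mean and SD of each metric across CV folds.

    SD is the sample standard deviation (ddof=1); a single fold yields
    SD 0.
    """
    rows = [r.to_dict() for r in reports]
    if not rows:
        raise ValueError("no fold reports to aggregate")
    df = pd.DataFrame(rows)
    out = pd.DataFrame(index=df.columns)
    out["mean"] = df.mean()
    out["sd"] = df.std(ddof=1).fillna(0.0) if len(df) > 1 else 0.0
    return out
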