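"""Two-stage feature selection and subject-wise nested cross-validation.

Stage 1 screens the 915 band-power features with a t-test between the two
classes (significance level 0.05 by default). Stage 2 runs recursive
feature elimination with internal cross-validation (RFECV) around a
random-forest classifier (Gini impurity, maximum depth 30): features are
dropped one at a time by lowest forest importance, each subset size is
scored by inner k-fold accuracy, and the size maximizing the mean inner
score wins (ties go to the smaller subset).

Generalization is estimated by a nested, subject-wise 10-fold
cross-validation: subjects are partitioned into ten outer groups, all
filtering and selection happens inside each outer training set (the
default ``within_fold`` scope; ``global_paper_mode`` instead applies the
t-test filter once to the full table before the loop, reproducing the
common but leakage-prone one-shot variant), and the forest is scored on
the held-out subjects. Each outer fold yields a confusion matrix and the
seven-metric report; the aggregate is the unweighted mean/SD across folds.

Pairing note: the paired t-test is only well defined on a balanced table
(the i-th engendered epoch is paired with the i-th subsampled
un-engendered epoch). Subject-wise outer splits leave training folds
slightly unbalanced, so ``within_fold`` filtering uses the unpaired
(Welch) test; ``kind='auto'`` picks paired exactly when counts match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV, SelectorMixin
from sklearn.model_selection import GroupKFold, StratifiedKFold

from . import metrics as metrics_mod
from .epochs import LABEL_ENGENDERED, LABEL_UNENGENDERED

__all__ = [
    "SelectionConfig",
    "TTestFilter",
    "ttest_filter",
    "build_classifier",
    "rfecv_select",
    "FoldResult",
    "CVResult",
    "nested_cv",
]


@dataclass
class SelectionConfig:
    """Settings for filtering, RFECV and the random forest."""

    alpha_filter: float = 0.05
    outer_folds: int = 10
    inner_folds: int = 10
    rfe_step: int = 1
    trees: int = 50
    max_depth: int = 30
    split_criterion: str = "gini"
    seed: int = 0
    filter_scope: str = "within_fold"  # or "global_paper_mode"
    ttest_kind: str = "auto"  # "paired" | "unpaired" | "auto"
    min_features: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.alpha_filter < 1:
            raise ValueError("alpha_filter must be in (0, 1)")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.filter_scope not in ("within_fold", "global_paper_mode"):
            raise ValueError("filter_scope must be 'within_fold' or 'global_paper_mode'")
        if self.ttest_kind not in ("paired", "unpaired", "auto"):
            raise ValueError("ttest_kind must be 'paired', 'unpaired' or 'auto'")
        if self.trees < 1 or self.rfe_step < 1 or self.min_features < 1:
            raise ValueError("trees, rfe_step and min_features must be positive")


def _binarize(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    known = {LABEL_ENGENDERED, LABEL_UNENGENDERED}
    bad = set(labels) - known
    if bad:
        raise ValueError(f"labels outside the two classes: {sorted(map(str, bad))}")
    return (labels == LABEL_ENGENDERED).astype(int)


class TTestFilter(SelectorMixin, BaseEstimator):
    """Univariate t-test screen: keep features with p < alpha.

    ``kind='paired'`` pairs the i-th positive with the i-th negative
    sample in row order (the matching induced by class balancing) and
    requires equal class counts; ``'unpaired'`` uses Welch's test;
    ``'auto'`` chooses paired iff the counts match. Features with an
    undefined statistic (zero variance) are never selected.
    """

    def __init__(self, alpha: float = 0.05, kind: str = "auto") -> None:
        self.alpha = alpha
        self.kind = kind

    def fit(self, X, y) -> "TTestFilter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if y.dtype == object or y.dtype.kind in "US":
            y = _binarize(y)
        pos, neg = X[y == 1], X[y == 0]
        if pos.shape[0] == 0 or neg.shape[0] == 0:
            raise ValueError("both classes required for the t-test filter")
        kind = self.kind
        if kind == "auto":
            kind = "paired" if pos.shape[0] == neg.shape[0] else "unpaired"
        if kind == "paired":
            if pos.shape[0] != neg.shape[0]:
                raise ValueError(
                    "paired t-test requires equal class counts "
                    f"(got {pos.shape[0]} vs {neg.shape[0]}); balance first or use kind='unpaired'"
                )
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_rel(pos, neg, axis=0)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
        self.kind_used_ = kind
        self.pvalues_ = np.asarray(p)
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self) -> np.ndarray:
        p = self.pvalues_
        return np.where(np.isnan(p), False, p < self.alpha)


def ttest_filter(features: pd.DataFrame, labels, alpha: float = 0.05,
                 kind: str = "auto") -> list[str]:
    """Names of the features passing the t-test screen."""
    filt = TTestFilter(alpha=alpha, kind=kind).fit(features.to_numpy(), labels)
    return [c for c, keep in zip(features.columns, filt.get_support()) if keep]


def build_classifier(config: SelectionConfig, seed: int | None = None) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=config.trees,
        criterion=config.split_criterion,
        max_depth=config.max_depth,
        random_state=config.seed if seed is None else seed,
    )


def rfecv_select(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    config: SelectionConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, RFECV]:
    """Recursive feature elimination with internal CV around the forest.

    Returns the boolean support mask over the input columns and the
    fitted :class:`~sklearn.feature_selection.RFECV` (its
    ``cv_results_`` holds the inner accuracy curve). Ties in the mean
    inner accuracy resolve to the smaller subset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype == object or y.dtype.kind in "US":
        y = _binarize(y)
    if np.unique(y).size < 2:
        raise ValueError("training fold contains a single class")
    if X.shape[1] < 1:
        raise ValueError("no features to select from")
    if X.shape[1] == 1:
        selector = None
        support = np.ones(1, dtype=bool)
        return support, selector
    seed = config.seed if seed is None else seed
    inner = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    selector = RFECV(
        estimator=build_classifier(config, seed),
        step=config.rfe_step,
        cv=inner,
        scoring="accuracy",
        min_features_to_select=config.min_features,
        n_jobs=None,
    )
    selector.fit(X, y)
    return selector.support_.copy(), selector


@dataclass
class FoldResult:
    """Outcome of one outer fold."""

    fold: int
    test_subjects: tuple[str, ...]
    selected_features: tuple[str, ...]
    confusion: metrics_mod.ConfusionMatrix
    report: metrics_mod.MetricsReport

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "test_subjects": list(self.test_subjects),
            "selected_features": list(self.selected_features),
            "confusion": asdict(self.confusion),
            "metrics": self.report.to_dict(),
        }


@dataclass
class CVResult:
    """Per-fold selections, confusion counts and metrics, plus aggregates."""

    folds: list[FoldResult] = field(default_factory=list)

    def reports(self) -> list[metrics_mod.MetricsReport]:
        return [f.report for f in self.folds]

    def summary(self) -> pd.DataFrame:
        """Per-fold metric table with a trailing mean/SD block."""
        rows = [f.report.to_dict() for f in self.folds]
        df = pd.DataFrame(rows, index=[f"fold {f.fold + 1}" for f in self.folds])
        agg = metrics_mod.aggregate(self.reports())
        df.loc["mean"] = agg["mean"]
        df.loc["sd"] = agg["sd"]
        return df

    def aggregate(self) -> pd.DataFrame:
        return metrics_mod.aggregate(self.reports())

    def subset_sizes(self) -> np.ndarray:
        return np.array([len(f.selected_features) for f in self.folds])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"folds": [f.to_dict() for f in self.folds]}, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, path: str | Path) -> "CVResult":
        payload = json.loads(Path(path).read_text())
        folds = []
        for f in payload["folds"]:
            cm = metrics_mod.ConfusionMatrix(**f["confusion"])
            rep = metrics_mod.MetricsReport(**f["metrics"])
            folds.append(
                FoldResult(
                    fold=f["fold"],
                    test_subjects=tuple(f["test_subjects"]),
                    selected_features=tuple(f["selected_features"]),
                    confusion=cm,
                    report=rep,
                )
            )
        return cls(folds=folds)


def _filter_columns(features: pd.DataFrame, labels, config: SelectionConfig,
                    kind: str) -> np.ndarray:
    """Boolean column mask from the t-test screen, with a smallest-p floor.

    If fewer than two features pass (possible in null/permutation runs on
    small tables), the two smallest p-values are kept so that RFECV
    remains well defined.
    """
    filt = TTestFilter(alpha=config.alpha_filter, kind=kind)
    filt.fit(features.to_numpy(), labels)
    mask = filt.get_support()
    if mask.sum() < 2:
        p = np.where(np.isnan(filt.pvalues_), np.inf, filt.pvalues_)
        mask = np.zeros_like(mask)
        mask[np.argsort(p)[:2]] = True
    return mask


def nested_cv(
    features: pd.DataFrame,
    labels: Sequence,
    subject_ids: Sequence,
    config: SelectionConfig,
) -> CVResult:
    """Nested, subject-wise cross-validation of the filter+RFECV+forest stack.

    Outer loop: subjects partitioned into ``config.outer_folds`` groups
    (no subject ever appears in both train and test of a fold). Inner
    loop: stratified ``config.inner_folds``-fold CV drives the RFECV
    subset-size choice. All randomness derives from ``config.seed``.
    """
    labels = np.asarray(labels, dtype=object)
    y = _binarize(labels)
    subject_ids = np.asarray([str(s) for s in subject_ids], dtype=object)
    if features.shape[0] != y.size or subject_ids.size != y.size:
        raise ValueError("features, labels and subject_ids must align")
    n_subjects = np.unique(subject_ids).size
    if n_subjects < config.outer_folds:
        raise ValueError(
            f"need at least {config.outer_folds} distinct subjects, got {n_subjects}"
        )

    fold_seeds = np.random.SeedSequence(config.seed).generate_state(config.outer_folds) % (2**31)
    global_mask = None
    if config.filter_scope == "global_paper_mode":
        kind = config.ttest_kind if config.ttest_kind != "auto" else "auto"
        global_mask = _filter_columns(features, labels, config, kind)

    X_all = features.to_numpy(dtype=float)
    columns = np.asarray(features.columns, dtype=object)
    result = CVResult()
    outer = GroupKFold(n_splits=config.outer_folds)
    for fold, (tr, te) in enumerate(outer.split(X_all, y, groups=subject_ids)):
        seed = int(fold_seeds[fold])
        if np.unique(y[tr]).size < 2:
            raise ValueError(f"outer fold {fold}: training data has a single class")
        if global_mask is not None:
            mask = global_mask
        else:
            kind = "unpaired" if config.ttest_kind == "auto" else config.ttest_kind
            mask = _filter_columns(
                features.iloc[tr], labels[tr], config, kind
            )
        Xtr, Xte = X_all[tr][:, mask], X_all[te][:, mask]
        support, _ = rfecv_select(Xtr, y[tr], config, seed=seed)
        selected = columns[mask][support]
        clf = build_classifier(config, seed)
        clf.fit(Xtr[:, support], y[tr])
        pred = clf.predict(Xte[:, support])
        scores = clf.predict_proba(Xte[:, support])[:, list(clf.classes_).index(1)]
        cm = metrics_mod.confusion(
            np.where(y[te] == 1, LABEL_ENGENDERED, LABEL_UNENGENDERED),
            np.where(pred == 1, LABEL_ENGENDERED, LABEL_UNENGENDERED),
        )
        try:
            auc_value = metrics_mod.auc(scores, y[te])
        except ValueError:
            auc_value = float("nan")
        report = metrics_mod.MetricsReport.from_confusion(cm, auc_value)
        result.folds.append(
            FoldResult(
                fold=fold,
                test_subjects=tuple(sorted(set(subject_ids[te]))),
                selected_features=tuple(selected),
                confusion=cm,
                report=report,
            )
        )
    return result
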