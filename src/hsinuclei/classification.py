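"""Linear SVM classification of irradiated vs non-irradiated nuclei.

For each (radiation type, band set, feature group) a linear support-vector
classifier is trained to separate irradiated nuclei from the shared
non-irradiated reference class.  The protocol: stratified 70/30
train/test split, per-feature min-max scaling fitted on the training set,
L2-regularized squared-hinge linear SVC with cost parameter C = 10, and
point metrics from the confusion counts:

    SEN  = TP / (TP + FN)             sensitivity
    ACC  = (TP + TN) / n              accuracy
    PREC = TP / (TP + FP)             precision
    F1   = 2 SEN PREC / (SEN + PREC)  harmonic mean

"Altered" means predicted irradiated.  On a set containing only irradiated
nuclei there are no FP/TN, so the irradiation efficiency E (fraction
predicted altered) coincides with SEN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import LinearSVC

from .spatial_features import ROUGHNESS_NAMES, TEXTURE_NAMES

__all__ = [
    "SplitConfig",
    "ConfusionCounts",
    "MetricsRecord",
    "metrics_from_counts",
    "f1_score",
    "stratified_split",
    "scale_minmax",
    "train_lsvc",
    "evaluate",
    "efficiency",
    "run_comparison",
]

GROUP_FEATURES = {"texture": list(TEXTURE_NAMES),
                  "roughness": list(ROUGHNESS_NAMES)}


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n_test(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsRecord:
    sen: float
    acc: float
    prec: float
    f1: float
    counts: ConfusionCounts | None = None
    context: tuple[str, str, str] | None = None  # (radiation, band, group)
    repeats: list["MetricsRecord"] = field(default_factory=list)


def f1_score(sen: float, prec: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both vanish."""
    if sen + prec == 0:
        return 0.0
    return 2.0 * sen * prec / (sen + prec)


def metrics_from_counts(counts: ConfusionCounts,
                        context=None) -> MetricsRecord:
    tp, fn, fp, tn = counts.tp, counts.fn, counts.fp, counts.tn
    sen = tp / (tp + fn) if tp + fn else 0.0
    acc = (tp + tn) / counts.n_test if counts.n_test else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    return MetricsRecord(sen=sen, acc=acc, prec=prec,
                         f1=f1_score(sen, prec), counts=counts,
                         context=context)


def stratified_split(y, cfg: SplitConfig, repeat: int = 0):
    """Deterministic stratified 70/30 split; returns (train_idx, test_idx).

    The training set holds ``floor(train_fraction * n)`` samples and the
    test set the ceiling complement, with per-label proportions preserved
    to within one sample (cohorts of 125 and 119 nuclei split 87/38 and
    83/36).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need two classes to split; got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("each label needs at least 2 samples")
    # test_size is left as the exact complement of the realized train count
    # (floor(train_fraction * n)); passing 1 - train_fraction would hit
    # floating-point rounding for some cohort sizes.
    splitter = StratifiedShuffleSplit(
        n_splits=1, train_size=cfg.train_fraction, test_size=None,
        random_state=cfg.seed + repeat)
    train_idx, test_idx = next(splitter.split(np.zeros((len(y), 1)), y))
    return np.sort(train_idx), np.sort(test_idx)


def scale_minmax(train: np.ndarray, test: np.ndarray):
    """Map each feature by the training min-max onto [0, 1].

    The same affine map is applied to the test set (values may leave
    [0, 1]; no clipping).  A zero-range training feature maps to 0
    everywhere in both sets.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    lo = train.min(axis=0)
    rng = train.max(axis=0) - lo
    scale = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
    return (train - lo) * scale, (test - lo) * scale


def train_lsvc(X_train: np.ndarray, y_train: np.ndarray,
               C: float = 10.0, loss: str = "squared_hinge") -> LinearSVC:
    """Fit the linear SVC (L2 penalty, squared-hinge loss, C = 10).

    ``loss="hinge"`` is exposed for sensitivity checks; the squared-hinge
    default matches the solver's standard configuration.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LinearSVC(C=C, loss=loss,
                    dual=(loss == "hinge"), random_state=0, max_iter=20000)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    return clf


def evaluate(clf, X_test: np.ndarray, y_test: np.ndarray,
             context=None) -> MetricsRecord:
    """Confusion counts and point metrics on a test set (1 = irradiated)."""
    y_test = np.asarray(y_test).astype(int)
    if len(y_test) == 0:
        raise ValueError("test set is empty")
    pred = np.asarray(clf.predict(np.asarray(X_test, dtype=float))).astype(int)
    tp = int(np.sum((y_test == 1) & (pred == 1)))
    fn = int(np.sum((y_test == 1) & (pred == 0)))
    fp = int(np.sum((y_test == 0) & (pred == 1)))
    tn = int(np.sum((y_test == 0) & (pred == 0)))
    return metrics_from_counts(ConfusionCounts(tp, fn, fp, tn),
                               context=context)


def efficiency(clf, X_irradiated: np.ndarray, y) -> float:
    """Fraction of an irradiated-only set predicted altered (equals SEN)."""
    y = np.asarray(y).astype(int)
    if np.any(y != 1):
        raise ValueError("efficiency is defined on irradiated-only sets")
    pred = np.asarray(clf.predict(np.asarray(X_irradiated,
                                             dtype=float))).astype(int)
    return float(np.mean(pred == 1))


def _aggregate(records: list[MetricsRecord], context) -> MetricsRecord:
    if len(records) == 1:
        return records[0]
    sen = float(np.mean([r.sen for r in records]))
    acc = float(np.mean([r.acc for r in records]))
    prec = float(np.mean([r.prec for r in records]))
    return MetricsRecord(sen=sen, acc=acc, prec=prec,
                         f1=f1_score(sen, prec), counts=None,
                         context=context, repeats=records)


def run_single(X: np.ndarray, y: np.ndarray, cfg: SplitConfig,
               C: float = 10.0, context=None,
               scale_on: str = "train") -> MetricsRecord:
    """One split/scale/train/test cycle, averaged over ``cfg.n_repeats``.

    ``scale_on="all"`` fits the min-max map on the pooled data instead of
    the training set only (for probing the leakage-prone variant).
    """
    per_repeat = []
    for r in range(cfg.n_repeats):
        train_idx, test_idx = stratified_split(y, cfg, repeat=r)
        if scale_on == "all":
            Xs, _ = scale_minmax(X, X)
            Xtr, Xte = Xs[train_idx], Xs[test_idx]
        else:
            Xtr, Xte = scale_minmax(X[train_idx], X[test_idx])
        clf = train_lsvc(Xtr, y[train_idx], C=C)
        per_repeat.append(evaluate(clf, Xte, y[test_idx], context=context))
    return _aggregate(per_repeat, context)


def run_comparison(feature_table: pd.DataFrame, radiation: str,
                   band_labels=None, groups=("texture", "roughness"),
                   cfg: SplitConfig | None = None, C: float = 10.0,
                   scale_on: str = "train") -> list[MetricsRecord]:
    """Train/evaluate one classifier per (band set, feature group).

    ``feature_table`` is the long table from
    :func:`hsinuclei.spatial_features.build_feature_table`; ``radiation``
    selects CI or XR, always against the shared REF class.  Rows are
    canonically sorted by nucleus_id before splitting, so input order does
    not affect results.
    """
    if radiation not in ("CI", "XR"):
        raise ValueError(f"radiation must be 'CI' or 'XR'; got {radiation!r}")
    cfg = cfg or SplitConfig()
    sub = feature_table[feature_table["class_label"].isin([radiation, "REF"])]
    if sub.empty or sub["class_label"].nunique() < 2:
        raise ValueError(
            f"feature table lacks {radiation} and/or REF nuclei")
    if band_labels is None:
        band_labels = list(dict.fromkeys(sub["band_label"]))

    records = []
    for band in band_labels:
        for group in groups:
            cols = GROUP_FEATURES[group]
            block = (sub[(sub["band_label"] == band)
                         & (sub["group"] == group)]
                     .sort_values("nucleus_id", kind="stable"))
            if block.empty:
                raise ValueError(
                    f"no rows for band {band!r}, group {group!r}")
            if block[cols].isna().any().any():
                raise ValueError(
                    f"missing feature values for band {band!r}, "
                    f"group {group!r}")
            X = block[cols].to_numpy(dtype=float)
            y = (block["class_label"] == radiation).to_numpy(dtype=int)
            records.append(run_single(X, y, cfg, C=C,
                                      context=(radiation, band, group),
                                      scale_on=scale_on))
    return records
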