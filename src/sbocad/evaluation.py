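"""Confusion-matrix bookkeeping and the five diagnostic indexes.

accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN); plus the repeated random-split protocol
(default 15 stratified 75/25 splits) used to report mean and spread of the
five indexes for a full train/test cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "metrics",
    "repeated_evaluation",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts; the shared currency of the MCC fitness and metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true, y_pred, positive=1) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with ``positive`` the cancerous-class label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must share a length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionMatrix(
        tp=int((t & p).sum()), fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; reporting 0", name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """The five diagnostic indexes of a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "sensitivity": _safe_ratio(cm.tp, cm.tp + cm.fn, "sensitivity"),
        "specificity": _safe_ratio(cm.tn, cm.tn + cm.fp, "specificity"),
        "ppv": _safe_ratio(cm.tp, cm.tp + cm.fp, "ppv"),
        "npv": _safe_ratio(cm.tn, cm.tn + cm.fn, "npv"),
    }


@dataclass
class MetricsReport:
    """Per-repeat metric values with their mean/std summary."""

    per_repeat: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)
    n_repeats: int = 0
    train_frac: float = 0.75
    seed: int = 0
    repeat_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_repeat": self.per_repeat,
            "mean": self.mean,
            "std": self.std,
            "n_repeats": self.n_repeats,
            "train_frac": self.train_frac,
            "seed": self.seed,
            "repeat_seeds": self.repeat_seeds,
        }


def repeat_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-repeat seeds derived from one master seed."""
    return [int(s) % (2 ** 31) for s in
            np.random.SeedSequence(master_seed).generate_state(n)]


def repeated_evaluation(features: np.ndarray, labels: np.ndarray, fit_predict,
                        n_repeats: int = 15, train_frac: float = 0.75,
                        seed: int = 0) -> MetricsReport:
    """Stratified random-split protocol around a train/predict callable.

    ``fit_predict(X_train, y_train, X_test, repeat_seed)`` must return the
    predicted labels for ``X_test``; predictions are scored against the held
    out labels with +1 as the positive (cancerous) class.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("two classes required")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members for stratification")
    seeds = repeat_seeds(seed, n_repeats)
    report = MetricsReport(n_repeats=n_repeats, train_frac=train_frac,
                           seed=seed, repeat_seeds=seeds)
    for rs in seeds:
        xtr, xte, ytr, yte = train_test_split(
            features, labels, train_size=train_frac, stratify=labels,
            random_state=rs)
        y_pred = fit_predict(xtr, ytr, xte, rs)
        cm = confusion(yte, y_pred, positive=1)
        row = metrics(cm)
        row["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        report.per_repeat.append(row)
    for name in METRIC_NAMES:
        vals = np.array([r[name] for r in report.per_repeat])
        report.mean[name] = float(vals.mean())
        report.std[name] = float(vals.std())
    return report
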