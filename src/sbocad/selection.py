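"""Wrapper feature selection driven by the bowerbird search.

A candidate subset is a point in [0, 1]^F decoded by thresholding at 0.5;
its quality is the Matthews correlation coefficient (MCC) of a stratified
k-fold cross-validated SVM restricted to the selected columns:

    MCC = (TP*TN - FP*FN) / sqrt((TN+FP)(TP+FP)(TP+FN)(TN+FN))

The search maximizes MCC (the optimizer minimizes its negation).  Subset
evaluations are memoized on the decoded mask, since many continuous
positions decode to the same subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import sbo as sbo_mod, svm as svm_mod
from .evaluation import ConfusionMatrix, confusion

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "FeatureMask",
    "mcc_fitness",
    "decode_mask",
    "evaluate_subset",
    "select_features",
]


@dataclass
class EvalConfig:
    """Cross-validation settings for scoring one feature subset."""

    n_folds: int = 5
    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0


@dataclass
class FeatureMask:
    """A selected subset with its achieved fitness and provenance."""

    mask: np.ndarray            # boolean over features
    fitness: float
    seed: int
    feature_names: tuple[str, ...] | None = None
    history: list[float] = field(default_factory=list)

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    def to_dict(self) -> dict:
        d = {
            "mask": [bool(v) for v in self.mask],
            "fitness": float(self.fitness),
            "seed": int(self.seed),
            "history": [float(v) for v in self.history],
        }
        if self.feature_names is not None:
            d["selected_features"] = [self.feature_names[i] for i in self.selected]
        return d


def mcc_fitness(cm: ConfusionMatrix) -> float:
    """Matthews correlation of a confusion matrix, in [-1, 1].

    A zero factor in the denominator yields 0 (the usual MCC convention);
    an all-zero matrix is rejected.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    if cm.total == 0:
        raise ValueError("all-zero confusion matrix")
    denom = (tn + fp) * (tp + fp) * (tp + fn) * (tn + fn)
    if denom == 0:
        logger.warning("zero factor in MCC denominator; reporting 0")
        return 0.0
    return ((tp * tn) - (fp * fn)) / math.sqrt(denom)


def decode_mask(position: np.ndarray) -> np.ndarray:
    """Threshold a continuous position at 0.5; an empty decode falls back to
    the single highest-valued coordinate so a subset is never empty."""
    position = np.asarray(position, dtype=float)
    mask = position >= 0.5
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def _canon_labels(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("two classes required")
    return np.where(labels == classes.max(), 1, -1)


def evaluate_subset(features: np.ndarray, labels: np.ndarray, mask: np.ndarray,
                    eval_config: EvalConfig | None = None) -> float:
    """Pooled cross-validated MCC of an SVM on the masked feature columns."""
    cfg = eval_config or EvalConfig()
    x = np.asarray(features, dtype=float)
    y = _canon_labels(np.asarray(labels))
    if x.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    mask = np.asarray(mask, dtype=bool)
    xm = x[:, mask]
    folds = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                            random_state=cfg.seed)
    y_true, y_pred = [], []
    for tr, te in folds.split(xm, y):
        model = svm_mod.train_svm(xm[tr], y[tr], kernel=cfg.kernel, C=cfg.C)
        y_true.append(y[te])
        y_pred.append(svm_mod.predict(model, xm[te]))
    cm = confusion(np.concatenate(y_true), np.concatenate(y_pred), positive=1)
    return mcc_fitness(cm)


def select_features(features: np.ndarray, labels: np.ndarray,
                    sbo_config: sbo_mod.SBOConfig | None = None,
                    eval_config: EvalConfig | None = None,
                    feature_names: tuple[str, ...] | None = None) -> FeatureMask:
    """Bowerbird search over [0, 1]^F maximizing the cross-validated MCC."""
    x = np.asarray(features, dtype=float)
    n_features = x.shape[1]
    cfg = eval_config or EvalConfig()
    if sbo_config is None:
        sbo_config = sbo_mod.SBOConfig(
            population_size=16, max_iterations=12, seed=cfg.seed,
            lower_bounds=np.zeros(n_features),
            upper_bounds=np.ones(n_features))
    cache: dict[bytes, float] = {}

    def objective(position):
        mask = decode_mask(position)
        key = mask.tobytes()
        if key not in cache:
            cache[key] = evaluate_subset(x, labels, mask, cfg)
        return -cache[key]

    result = sbo_mod.optimize(objective, sbo_config)
    mask = decode_mask(result.best_position)
    fitness = cache[mask.tobytes()]
    return FeatureMask(mask=mask, fitness=fitness, seed=sbo_config.seed,
                       feature_names=feature_names,
                       history=[-v for v in result.history])
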