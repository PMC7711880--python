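"""Kernel SVM for the final cancerous/healthy decision.

The dual problem is solved by scikit-learn's SMO; the decision surface

    y = sgn( sum_i y_i alpha_i K(x, x_i) + b )

is then evaluated directly from the stored support vectors, multipliers and
bias, so the prediction path is the explicit kernel sum rather than an
opaque library call.  Features are z-scored per column with the scaling
parameters stored in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from . import evaluation, sbo as sbo_mod

__all__ = ["SVMModel", "train_svm", "decision_value", "predict", "tune_svm"]


@dataclass
class SVMModel:
    support_vectors: np.ndarray   # standardized
    sv_labels: np.ndarray         # y_i in {-1, +1}
    alphas: np.ndarray            # alpha_i >= 0
    bias: float
    kernel: str                   # "linear" or "rbf"
    gamma: float                  # rbf width (ignored for linear)
    C: float
    scale_mean: np.ndarray
    scale_std: np.ndarray
    kernel_params: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]


def _kernel_matrix(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """K(x_row, sv) for every (row, support vector) pair."""
    sv = model.support_vectors
    if model.kernel == "linear":
        return x @ sv.T
    if model.kernel == "rbf":
        d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-model.gamma * d2)
    raise ValueError(f"unsupported kernel {model.kernel!r}")


def train_svm(features: np.ndarray, labels: np.ndarray, kernel: str = "rbf",
              C: float = 1.0, gamma: float | str = "scale") -> SVMModel:
    """Fit the dual SVM on z-scored features.

    ``labels`` must contain both classes, coded -1/+1 (any two-valued coding
    is mapped onto -1/+1 with the larger value positive).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training labels must contain exactly two classes")
    y = np.where(y == classes.max(), 1, -1)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    xs = (x - mean) / std
    clf = SVC(kernel=kernel, C=C, gamma=gamma)
    clf.fit(xs, y)
    gamma_val = float(clf._gamma) if kernel == "rbf" else 0.0
    dual = clf.dual_coef_[0]          # y_i * alpha_i
    model = SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        sv_labels=np.sign(dual).astype(int),
        alphas=np.abs(dual),
        bias=float(clf.intercept_[0]),
        kernel=kernel,
        gamma=gamma_val,
        C=float(C),
        scale_mean=mean,
        scale_std=std,
    )
    return model


def decision_value(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """Pre-sign decision values sum_i y_i alpha_i K(x, x_i) + b."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != len(model.scale_mean):
        raise ValueError("feature dimension mismatch")
    xs = (x - model.scale_mean) / model.scale_std
    k = _kernel_matrix(model, xs)
    return k @ (model.sv_labels * model.alphas) + model.bias


def predict(model: SVMModel, x: np.ndarray) -> np.ndarray:
    """Class labels in {-1, +1}; a decision value of exactly 0 maps to +1."""
    v = decision_value(model, x)
    return np.where(v >= 0, 1, -1)


def save_model(model: SVMModel, path) -> None:
    """Serialize a model to JSON (support vectors stored as nested lists)."""
    import json
    from pathlib import Path

    payload = {
        "support_vectors": model.support_vectors.tolist(),
        "sv_labels": model.sv_labels.tolist(),
        "alphas": model.alphas.tolist(),
        "bias": model.bias,
        "kernel": model.kernel,
        "gamma": model.gamma,
        "C": model.C,
        "scale_mean": model.scale_mean.tolist(),
        "scale_std": model.scale_std.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SVMModel:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return SVMModel(
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        sv_labels=np.asarray(d["sv_labels"], dtype=int),
        alphas=np.asarray(d["alphas"], dtype=float),
        bias=float(d["bias"]),
        kernel=d["kernel"],
        gamma=float(d["gamma"]),
        C=float(d["C"]),
        scale_mean=np.asarray(d["scale_mean"], dtype=float),
        scale_std=np.asarray(d["scale_std"], dtype=float),
    )


def tune_svm(features: np.ndarray, labels: np.ndarray, kernel: str = "rbf",
             n_folds: int = 3, sbo_config: sbo_mod.SBOConfig | None = None,
             seed: int = 0):
    """Optional SBO tuning of (log10 C, log10 gamma) by cross-validated MCC.

    Off the default pipeline path; returns ((C, gamma), OptimizationResult).
    """
    from sklearn.model_selection import StratifiedKFold

    from .selection import mcc_fitness

    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if sbo_config is None:
        sbo_config = sbo_mod.SBOConfig(
            population_size=10, max_iterations=8, seed=seed,
            lower_bounds=np.array([-2.0, -3.0]),
            upper_bounds=np.array([2.0, 1.0]))

    def objective(vec):
        c, g = 10.0 ** vec[0], 10.0 ** vec[1]
        folds = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        yt, yp = [], []
        for tr, te in folds.split(x, y):
            model = train_svm(x[tr], y[tr], kernel=kernel, C=c, gamma=g)
            yt.append(y[te])
            yp.append(predict(model, x[te]))
        cm = evaluation.confusion(np.concatenate(yt), np.concatenate(yp), positive=1)
        return -mcc_fitness(cm)

    result = sbo_mod.optimize(objective, sbo_config)
    c, g = 10.0 ** result.best_position[0], 10.0 ** result.best_position[1]
    return (float(c), float(g)), result
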