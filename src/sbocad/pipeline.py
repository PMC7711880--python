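"""End-to-end orchestration of the diagnosis chain.

Stages, in order: synthesize (or load) a dataset -> median-filter denoising
-> CNN patch-classifier segmentation (hybrid gradient-descent + bowerbird
training) -> per-lesion feature extraction -> repeated stratified 75/25
evaluation where each repeat runs bowerbird wrapper feature selection on the
training split, fits the SVM and scores the held-out split.

All stage outputs can be persisted under an output directory (filtered
images, masks, features.csv, selection mask, report.json); every artifact
records the master seed and a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnn, evaluation, selection, svm as svm_mod
from . import sbo as sbo_mod
from .features import FEATURE_NAMES, extract_all
from .preprocessing import median_filter, save_image, to_grayscale
from .synth import SyntheticDataset, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "dice"]

ALL_STAGES = ("synth", "preprocess", "segment", "features", "evaluate")


@dataclass
class PipelineConfig:
    """Every knob of the five-stage run, with desk-scale defaults.

    ``segmentation`` may be "cnn" (train and apply the patch classifier) or
    "oracle" (use the generator's ground-truth masks; useful for ablations
    of the downstream stages).
    """

    seed: int = 1
    # data
    n_images: int = 200
    benign_frac: float = 0.5
    difficulty: float = 1.0
    side: int = 256
    # preprocessing
    median_window: int = 3
    # segmentation
    segmentation: str = "cnn"
    patch_size: int = 16
    patch_stride: int = 4
    train_images: int = 24
    patches_per_image: int = 30
    gd_iterations: int = 300
    learning_rate: float = 0.1
    theta: float = 1e-4
    sbo_refine_enabled: bool = True
    sbo_refine_population: int = 16
    sbo_refine_iterations: int = 5
    sbo_refine_delta: float = 0.2
    sbo_refine_subsample: int = 400
    # feature selection (per evaluation repeat)
    selection_population: int = 16
    selection_iterations: int = 10
    selection_folds: int = 5
    selection_C: float = 1.0
    selection_kernel: str = "linear"
    # final classifier
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    # evaluation protocol
    n_repeats: int = 15
    train_frac: float = 0.75
    # artifacts
    out_dir: str | None = None
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Overlap 2|A∩B| / (|A| + |B|) between two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (pred & truth).sum() / denom


def _train_segmenter(grays, masks, config: PipelineConfig) -> cnn.PatchNet:
    rng = np.random.default_rng(config.seed)
    k = min(config.train_images, len(grays))
    x, d = cnn.sample_patches(grays[:k], masks[:k], config.patch_size,
                              config.patches_per_image, rng)
    net = cnn.patch_architecture(patch_size=config.patch_size, channels=1,
                                 seed=config.seed)
    tc = cnn.TrainConfig(learning_rate=config.learning_rate,
                         iterations=config.gd_iterations, theta=config.theta,
                         dropout_active=False, seed=config.seed)
    cnn.gd_train(net, x, d, tc)
    if config.sbo_refine_enabled:
        sub = min(config.sbo_refine_subsample, len(x))
        idx = rng.choice(len(x), size=sub, replace=False)
        theta0 = net.get_params()
        sconf = sbo_mod.SBOConfig(
            population_size=config.sbo_refine_population,
            max_iterations=config.sbo_refine_iterations,
            lower_bounds=theta0 - config.sbo_refine_delta,
            upper_bounds=theta0 + config.sbo_refine_delta,
            seed=config.seed)
        cnn.sbo_refine(net, x[idx], d[idx], sconf)
    return net


def _make_fit_predict(config: PipelineConfig, feature_names):
    """One evaluation repeat: select features on the train split, fit the
    SVM on the selected columns, predict the held-out split."""

    def fit_predict(xtr, ytr, xte, repeat_seed):
        sconf = sbo_mod.SBOConfig(
            population_size=config.selection_population,
            max_iterations=config.selection_iterations,
            lower_bounds=np.zeros(xtr.shape[1]),
            upper_bounds=np.ones(xtr.shape[1]),
            seed=repeat_seed)
        econf = selection.EvalConfig(n_folds=config.selection_folds,
                                     kernel=config.selection_kernel,
                                     C=config.selection_C, seed=repeat_seed)
        fmask = selection.select_features(xtr, ytr, sconf, econf,
                                          feature_names=feature_names)
        model = svm_mod.train_svm(xtr[:, fmask.mask], ytr,
                                  kernel=config.svm_kernel, C=config.svm_C)
        fit_predict.last_mask = fmask
        return svm_mod.predict(model, xte[:, fmask.mask])

    fit_predict.last_mask = None
    return fit_predict


def run_pipeline(config: PipelineConfig,
                 dataset: SyntheticDataset | None = None) -> dict:
    """Execute the staged chain and return the report dictionary.

    The report carries the five diagnostic indexes (mean/std over repeats),
    the mean segmentation Dice against the generator's ground truth, stage
    timings, the master seed and the config hash.
    """
    timings: dict[str, float] = {}
    report: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "config": config.to_dict()}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if dataset is None:
        dataset = generate_dataset(config.n_images, config.benign_frac,
                                   config.difficulty, seed=config.seed,
                                   side=config.side)
    timings["synth"] = time.perf_counter() - t0
    logger.info("stage synth: %d images (%.2fs)", len(dataset), timings["synth"])
    if "preprocess" not in config.stages:
        report["timings"] = timings
        return report

    t0 = time.perf_counter()
    grays = [median_filter(to_grayscale(img), config.median_window)
             for img in dataset.images]
    timings["preprocess"] = time.perf_counter() - t0
    logger.info("stage preprocess done (%.2fs)", timings["preprocess"])
    if "segment" not in config.stages:
        report["timings"] = timings
        return report

    t0 = time.perf_counter()
    if config.segmentation == "oracle":
        pred_masks = [m.copy() for m in dataset.masks]
    elif config.segmentation == "cnn":
        net = _train_segmenter(grays, dataset.masks, config)
        pred_masks = [cnn.segment(g, net, config.patch_size,
                                  config.patch_stride) for g in grays]
    else:
        raise ValueError(f"unknown segmentation mode {config.segmentation!r}")
    dices = [dice(p, t) for p, t in zip(pred_masks, dataset.masks)]
    report["mean_dice"] = float(np.mean(dices))
    timings["segment"] = time.perf_counter() - t0
    logger.info("stage segment: mean Dice %.3f (%.2fs)",
                report["mean_dice"], timings["segment"])
    if out_dir:
        mdir = out_dir / "pred_masks"
        mdir.mkdir(exist_ok=True)
        for i, m in enumerate(pred_masks):
            save_image(mdir / f"im_{i:04d}.png", m)
    if "features" not in config.stages:
        report["timings"] = timings
        return report

    t0 = time.perf_counter()
    rows, keep_labels = [], []
    n_empty = 0
    for gray, mask, label in zip(grays, pred_masks, dataset.labels):
        if not mask.any():
            n_empty += 1
            continue
        rows.append(extract_all(gray, mask))
        keep_labels.append(label)
    if n_empty:
        logger.warning("%d images produced empty masks and were dropped", n_empty)
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    y = np.where(np.asarray(keep_labels) == "malignant", 1, -1)
    timings["features"] = time.perf_counter() - t0
    logger.info("stage features: %d rows (%.2fs)", len(table), timings["features"])
    if out_dir:
        table.assign(label=keep_labels).to_csv(out_dir / "features.csv",
                                               index=False)
    if "evaluate" not in config.stages:
        report["timings"] = timings
        return report

    t0 = time.perf_counter()
    fit_predict = _make_fit_predict(config, FEATURE_NAMES)
    mreport = evaluation.repeated_evaluation(
        table.to_numpy(), y, fit_predict, n_repeats=config.n_repeats,
        train_frac=config.train_frac, seed=config.seed)
    timings["evaluate"] = time.perf_counter() - t0
    report["metrics"] = mreport.to_dict()
    report["n_images_used"] = len(table)
    report["timings"] = timings
    logger.info("stage evaluate: mean accuracy %.3f (%.2fs)",
                mreport.mean["accuracy"], timings["evaluate"])
    if out_dir:
        if fit_predict.last_mask is not None:
            (out_dir / "mask.json").write_text(
                json.dumps(fit_predict.last_mask.to_dict(), indent=1))
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report
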