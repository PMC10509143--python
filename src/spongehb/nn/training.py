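"""Training loop, inference and cross-validation for the CNN regressors.

The loss is the composite

    L = MSE(pred, target) + lambda * L1(pred, target)

computed on targets divided by ``config.target_scale`` (masses of
hundreds of mg are rescaled to O(1) for optimizer stability; predictions
are rescaled back to mg at inference). The optimizer is Adam at the
configured learning rate. All randomness (weight init, shuffling) is
driven by ``config.seed``, so a run is exactly repeatable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from ..evaluation import AgreementReport, MetricSet, bland_altman, compute_metrics
from .resnet import KindName, RegressorConfig, ResNetRegressor, build_regressor

__all__ = [
    "Adam",
    "composite_loss",
    "preprocess_images",
    "train_regressor",
    "predict_mass",
    "predict_masses",
    "kfold_indices",
    "kfold_cv",
    "save_regressor",
    "load_regressor",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite; carries the offending epoch index."""

    def __init__(self, epoch: int) -> None:
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


class Adam:
    """Adaptive-moment optimizer (standard bias-corrected form)."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def composite_loss(
    pred: np.ndarray, target: np.ndarray, l1_weight: float
) -> tuple[float, np.ndarray]:
    """MSE + lambda*L1 and its gradient with respect to ``pred``."""
    diff = pred - target
    n = diff.size
    loss = float(np.mean(diff**2) + l1_weight * np.mean(np.abs(diff)))
    grad = 2.0 * diff / n + l1_weight * np.sign(diff) / n
    return loss, grad


def preprocess_images(images: Sequence[np.ndarray], input_size: int) -> np.ndarray:
    """Resize crops to ``input_size`` squares and normalize to [-0.5, 0.5].

    Returns a float64 NCHW batch.
    """
    batch = np.empty((len(images), 3, input_size, input_size), dtype=np.float64)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"image {i}: expected HxWx3, got shape {arr.shape}")
        arr = arr.astype(np.float64) / 255.0 if arr.dtype == np.uint8 else arr.astype(np.float64)
        if arr.shape[0] != input_size or arr.shape[1] != input_size:
            arr = resize(arr, (input_size, input_size), anti_aliasing=True)
        batch[i] = arr.transpose(2, 0, 1) - 0.5
    return batch


def train_regressor(
    model: ResNetRegressor,
    images: Sequence[np.ndarray],
    masses: Sequence[float],
    config: RegressorConfig | None = None,
) -> ResNetRegressor:
    """Fit the regressor on (image, Hb mass mg) pairs in place.

    Records per-epoch mean training loss (in scaled target units) in
    ``model.history``. Raises :class:`TrainingDivergedError` with the
    epoch index if the loss goes non-finite.
    """
    config = config if config is not None else model.config
    masses = np.asarray(masses, dtype=np.float64)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != masses.size:
        raise ValueError("images and masses must have equal length")

    x = preprocess_images(images, config.input_size)
    y = masses / config.target_scale

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    n = len(images)

    model.history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            opt.zero_grad()
            pred = model.forward(x[idx], train=True)
            loss, grad = composite_loss(pred, y[idx], config.l1_weight)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        model.history.append(epoch_loss / n_batches)

    model.trained = True
    return model


def predict_masses(model: ResNetRegressor, images: Sequence[np.ndarray]) -> np.ndarray:
    """Raw (unclamped) predicted Hb masses in mg, order-preserving."""
    if not model.trained:
        raise RuntimeError("model is untrained; call train_regressor first")
    if len(images) == 0:
        return np.empty(0)
    x = preprocess_images(images, model.config.input_size)
    preds = []
    bs = max(1, model.config.batch_size)
    for start in range(0, len(images), bs):
        preds.append(model.forward(x[start : start + bs], train=False))
    return np.concatenate(preds) * model.config.target_scale


def predict_mass(model: ResNetRegressor, image: np.ndarray) -> float:
    """Clamped (>= 0 mg) predicted Hb mass for one crop."""
    raw = float(predict_masses(model, [image])[0])
    return max(0.0, raw)


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """One shuffle, then k contiguous folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k ({k}) exceeds dataset size ({n})")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def kfold_cv(
    images: Sequence[np.ndarray],
    masses: Sequence[float],
    *,
    kind: KindName = "se_resnet",
    config: RegressorConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """k-fold cross-validation: train on k-1 folds, score the held-out one.

    Returns per-fold metric sets and agreement reports plus the mean/SD
    of MAE, MAPE and R^2 across folds.
    """
    masses = np.asarray(masses, dtype=np.float64)
    config = config if config is not None else RegressorConfig.tiny(seed=seed)
    folds = kfold_indices(len(images), k, seed)
    all_idx = np.arange(len(images))

    fold_metrics: list[MetricSet] = []
    fold_agreement: list[AgreementReport] = []
    for fold in folds:
        train_idx = np.setdiff1d(all_idx, fold)
        model = build_regressor(kind, config)
        train_regressor(model, [images[i] for i in train_idx], masses[train_idx], config)
        preds = predict_masses(model, [images[i] for i in fold])
        fold_metrics.append(compute_metrics(masses[fold], preds))
        fold_agreement.append(bland_altman(preds, masses[fold]))

    arr = np.array([[m.mae, m.mape, m.r2] for m in fold_metrics])
    return {
        "folds": fold_metrics,
        "agreement": fold_agreement,
        "mean": MetricSet(*arr.mean(axis=0)),
        "sd": MetricSet(*arr.std(axis=0, ddof=1)),
    }


def save_regressor(model: ResNetRegressor, path: str | Path) -> None:
    """Serialize parameters, BN statistics, config and history (.npz)."""
    from dataclasses import asdict

    from .layers import BatchNorm2d

    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    bns = [l for l in _iter_bn(model)]
    for i, bn in enumerate(bns):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    meta = {
        "kind": model.kind,
        "config": asdict(model.config),
        "trained": model.trained,
        "history": model.history,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_regressor(path: str | Path) -> ResNetRegressor:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = RegressorConfig(**meta["config"])
        model = build_regressor(meta["kind"], config)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i}"]
        for i, bn in enumerate(_iter_bn(model)):
            bn.running_mean[...] = data[f"bn_mean_{i}"]
            bn.running_var[...] = data[f"bn_var_{i}"]
    model.trained = bool(meta["trained"])
    model.history = list(meta["history"])
    return model


def _iter_bn(model: ResNetRegressor):
    from .layers import BatchNorm2d
    from .resnet import Bottleneck

    for layer in model.layers:
        if isinstance(layer, BatchNorm2d):
            yield layer
        elif isinstance(layer, Bottleneck):
            yield layer.bn1
            yield layer.bn2
            yield layer.bn3
            if layer.proj_bn is not None:
                yield layer.proj_bn


def history_to_csv(model: ResNetRegressor, path: str | Path) -> None:
    pd.DataFrame(
        {"epoch": np.arange(1, len(model.history) + 1), "loss": model.history}
    ).to_csv(path, index=False)
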