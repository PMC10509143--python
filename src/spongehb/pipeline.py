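"""End-to-end experiment orchestration.

Mirrors the full study protocol: render (or load) a sponge dataset with
known Hb masses, split it 7:3 into training and testing groups, fit the
requested predictors (color-moment linear regression and/or the CNN
regressors), and score every model on the held-out test group with MAE,
MAPE, R^2 and Bland-Altman agreement. A batch-prediction entry point
totals per-sponge predictions into a running surgical Hb loss, the role
the interactive upload interface plays in the clinical workflow.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, linear, roi, synthetic
from .nn import RegressorConfig, build_regressor, predict_masses, train_regressor

__all__ = [
    "ExperimentConfig",
    "BatchPrediction",
    "HbRegressor",
    "LinearPredictor",
    "CnnPredictor",
    "split_dataset",
    "run_experiment",
    "predict_batch",
]

MODEL_NAMES = ("feature_extraction", "resnet", "se_resnet")


class HbRegressor(Protocol):
    """Common contract of all predictors: sponge crop -> raw Hb mass (mg)."""

    name: str

    def predict(self, crops: Sequence[np.ndarray]) -> np.ndarray: ...


@dataclass
class LinearPredictor:
    """Color-moment features + OLS, wrapped as an :class:`HbRegressor`."""

    coeffs: linear.LinearCoefficients
    sponge_base_color: tuple[float, float, float]
    region: str = "crop"
    name: str = "feature_extraction"

    def predict(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        return np.array(
            [
                linear.predict_linear(
                    self.coeffs,
                    features.extract_features(
                        c, self.sponge_base_color, region=self.region
                    ),
                )
                for c in crops
            ]
        )


@dataclass
class CnnPredictor:
    """A trained CNN regressor wrapped as an :class:`HbRegressor`."""

    model: object  # ResNetRegressor
    name: str = "se_resnet"

    def predict(self, crops: Sequence[np.ndarray]) -> np.ndarray:
        return predict_masses(self.model, crops)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment run needs; YAML-serializable."""

    n_images: int = 120
    concentration_range: tuple[float, float] = synthetic.DEFAULT_CONCENTRATION_RANGE
    volume_range: tuple[float, float] = synthetic.DEFAULT_VOLUME_RANGE
    scene_size: int = 128  # rendered frame edge, px (scaled default scene)
    noise_sd: float = 2.0
    split_ratio: float = 0.7
    models: tuple[str, ...] = ("feature_extraction",)
    regressor: RegressorConfig = field(default_factory=lambda: RegressorConfig.tiny())
    feature_region: str = "crop"
    seed: int = 0
    out_dir: str = "experiment_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split ratio must lie strictly between 0 and 1")
        if not self.models:
            raise ValueError("at least one model must be requested")
        for m in self.models:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model {m!r}: choose from {MODEL_NAMES}")

    def scene(self) -> synthetic.SceneParams:
        base = synthetic.SceneParams().scaled(self.scene_size)
        return replace(base, noise_sd=self.noise_sd)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        reg = raw.pop("regressor", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if reg is not None:
            cfg = replace(cfg, regressor=RegressorConfig(**reg))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        from dataclasses import asdict

        payload = asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass(frozen=True)
class BatchPrediction:
    """Per-image predictions plus the running total surgical Hb loss."""

    per_image: tuple[float, ...]
    count: int
    total: float
    skipped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.count != len(self.per_image):
            raise ValueError("count must equal the number of per-image predictions")
        if not math.isclose(self.total, sum(self.per_image), abs_tol=1e-9):
            raise ValueError("total must equal the sum of per-image predictions")


def split_dataset(
    manifest: pd.DataFrame, ratio: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, disjoint train/test split; training size = floor(ratio * n).

    Flooring reproduces e.g. 851 records -> 595 train / 256 test at the
    7:3 default ratio.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must lie strictly between 0 and 1, got {ratio}")
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    n = len(manifest)
    n_train = int(math.floor(ratio * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = manifest.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = manifest.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def _load_and_crop(
    image_dir: Path, manifest: pd.DataFrame, scene: synthetic.SceneParams
) -> list[np.ndarray]:
    crops = []
    for filename in manifest["filename"]:
        img = iio.imread(image_dir / filename)
        box = roi.detect_sponge_region(img, scene.background_color)
        crops.append(roi.crop(img, box))
    return crops


def _fit_predictor(
    name: str,
    train_crops: list[np.ndarray],
    train_masses: np.ndarray,
    config: ExperimentConfig,
) -> HbRegressor:
    scene = config.scene()
    if name == "feature_extraction":
        fvs = [
            features.extract_features(
                c, scene.sponge_base_color, region=config.feature_region
            )
            for c in train_crops
        ]
        coeffs = linear.fit_linear(fvs, train_masses)
        return LinearPredictor(
            coeffs, scene.sponge_base_color, region=config.feature_region
        )
    kind = "se_resnet" if name == "se_resnet" else "resnet"
    reg_cfg = replace(config.regressor, seed=config.regressor.seed)
    model = build_regressor(kind, reg_cfg)
    train_regressor(model, train_crops, train_masses, reg_cfg)
    return CnnPredictor(model, name=name)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full protocol and write CSV/JSON reports.

    Writes to ``config.out_dir``:

    * ``images/`` + ``images/manifest.csv`` — the rendered dataset,
    * ``predictions.csv`` — per-test-image actual, raw and clamped
      predictions for every model,
    * ``metrics.csv`` — one row per model: MAE (mg), MAPE (%), R^2,
    * ``agreement.csv`` — bias and LOA with 95% CIs per model,
    * ``improvements.csv`` — pairwise model improvement table,
    * ``summary.json`` — everything above, deterministic byte-for-byte
      under a fixed config (no timestamps; keys sorted).

    Returns the summary as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = config.scene()

    image_dir = out / "images"
    manifest = synthetic.generate_dataset(
        config.n_images,
        image_dir,
        concentration_range=config.concentration_range,
        volume_range=config.volume_range,
        scene=scene,
        seed=config.seed,
    )
    train_m, test_m = split_dataset(manifest, config.split_ratio, seed=config.seed)

    train_crops = _load_and_crop(image_dir, train_m, scene)
    test_crops = _load_and_crop(image_dir, test_m, scene)
    train_y = train_m["hb_mass_mg"].to_numpy()
    test_y = test_m["hb_mass_mg"].to_numpy()

    pred_frame = pd.DataFrame(
        {"filename": test_m["filename"], "actual_mg": test_y}
    )
    metrics: dict[str, evaluation.MetricSet] = {}
    agreements: dict[str, evaluation.AgreementReport] = {}
    for name in config.models:
        predictor = _fit_predictor(name, train_crops, train_y, config)
        raw = predictor.predict(test_crops)
        pred_frame[f"{name}_raw_mg"] = raw
        pred_frame[f"{name}_reported_mg"] = np.maximum(raw, 0.0)
        metrics[name] = evaluation.compute_metrics(test_y, raw)
        agreements[name] = evaluation.bland_altman(raw, test_y)

    pred_frame.to_csv(out / "predictions.csv", index=False)

    metrics_rows = [
        {"algorithm": name, "mae_mg": m.mae, "mape_pct": m.mape, "r2": m.r2}
        for name, m in metrics.items()
    ]
    pd.DataFrame(metrics_rows).to_csv(out / "metrics.csv", index=False)

    agree_rows = []
    for name, rep in agreements.items():
        agree_rows.append(
            {
                "algorithm": name,
                "bias_mg": rep.bias,
                "bias_ci_lo": rep.ci_bias[0],
                "bias_ci_hi": rep.ci_bias[1],
                "loa_lower_mg": rep.loa_lower,
                "loa_lower_ci_lo": rep.ci_loa_lower[0],
                "loa_lower_ci_hi": rep.ci_loa_lower[1],
                "loa_upper_mg": rep.loa_upper,
                "loa_upper_ci_lo": rep.ci_loa_upper[0],
                "loa_upper_ci_hi": rep.ci_loa_upper[1],
                "n": rep.n,
            }
        )
    pd.DataFrame(agree_rows).to_csv(out / "agreement.csv", index=False)

    improvements = None
    if len(metrics) >= 2:
        improvements = evaluation.compare_models(metrics)
        improvements.to_csv(out / "improvements.csv", index=False)

    summary = {
        "config": {
            "n_images": config.n_images,
            "concentration_range": list(config.concentration_range),
            "volume_range": list(config.volume_range),
            "scene_size": config.scene_size,
            "noise_sd": config.noise_sd,
            "split_ratio": config.split_ratio,
            "models": list(config.models),
            "seed": config.seed,
        },
        "n_train": int(len(train_m)),
        "n_test": int(len(test_m)),
        "metrics": {k: vars(m) for k, m in metrics.items()},
        "agreement": {
            k: {
                "bias": rep.bias,
                "sd_diff": rep.sd_diff,
                "loa_lower": rep.loa_lower,
                "loa_upper": rep.loa_upper,
                "ci_bias": list(rep.ci_bias),
                "ci_loa_lower": list(rep.ci_loa_lower),
                "ci_loa_upper": list(rep.ci_loa_upper),
                "n": rep.n,
            }
            for k, rep in agreements.items()
        },
        "improvements": improvements.to_dict("records") if improvements is not None else [],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def predict_batch(
    image_paths: Sequence[str | Path],
    predictor: HbRegressor,
    background_color: Sequence[float],
) -> BatchPrediction:
    """Detect, crop and predict each image; total the clamped masses.

    Unreadable or sponge-free images are skipped with a warning and
    listed in the report; if every image fails, an error is raised.
    """
    preds: list[float] = []
    skipped: list[str] = []
    for path in image_paths:
        try:
            img = iio.imread(path)
            box = roi.detect_sponge_region(img, background_color)
            crop_arr = roi.crop(img, box)
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping {path}: {exc}", stacklevel=2)
            skipped.append(str(path))
            continue
        raw = float(predictor.predict([crop_arr])[0])
        preds.append(max(0.0, raw))
    if image_paths and not preds:
        raise RuntimeError("no readable sponge image in the batch")
    return BatchPrediction(
        per_image=tuple(preds),
        count=len(preds),
        total=float(sum(preds)),
        skipped=tuple(skipped),
    )
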