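"""Linear regression predictor: Hb mass (mg) from the four color features.

The model is plain ordinary least squares,

    y_hat = b0 + b1*X1 + b2*X2 + b3*X3 + b4*X4,

with no regularization or feature selection. Negative predicted masses
are physically impossible, so the pipeline clamps reported values at
0 mg; the raw (unclamped) prediction is what enters evaluation metrics,
keeping the metrics faithful to the fitted model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .features import FeatureVector

__all__ = [
    "LinearCoefficients",
    "fit_linear",
    "predict_linear",
    "clamp_mass",
]


@dataclass(frozen=True)
class LinearCoefficients:
    """Fitted OLS coefficients; ``stderr`` are their standard errors."""

    b0: float
    b1: float
    b2: float
    b3: float
    b4: float
    stderr: tuple[float, float, float, float, float] | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b1, self.b2, self.b3, self.b4])

    def to_json(self, path: str | Path) -> None:
        payload = {f"b{i}": float(b) for i, b in enumerate(self.as_array())}
        if self.stderr is not None:
            payload["stderr"] = [float(s) for s in self.stderr]
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearCoefficients":
        payload = json.loads(Path(path).read_text())
        stderr = payload.get("stderr")
        return cls(
            *(float(payload[f"b{i}"]) for i in range(5)),
            stderr=tuple(stderr) if stderr is not None else None,
        )


def _design_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    x = np.stack([f.as_array() for f in features])
    return sm.add_constant(x, has_constant="add")


def fit_linear(
    features: Sequence[FeatureVector], targets: Sequence[float]
) -> LinearCoefficients:
    """Ordinary least squares fit of Hb mass (mg) on (X1..X4).

    Requires at least 5 samples and a full-rank design matrix (the model
    has 5 parameters including the intercept).
    """
    targets = np.asarray(targets, dtype=np.float64)
    if len(features) != targets.size:
        raise ValueError("features and targets must have equal length")
    if len(features) < 5:
        raise ValueError(
            f"need at least 5 samples to fit 5 coefficients, got {len(features)}"
        )
    design = _design_matrix(features)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "design matrix is rank deficient: the four features (plus "
            "intercept) are linearly dependent on this sample"
        )
    fit = sm.OLS(targets, design).fit()
    return LinearCoefficients(*map(float, fit.params), stderr=tuple(map(float, fit.bse)))


def predict_linear(coeffs: LinearCoefficients, x: FeatureVector) -> float:
    """Raw (unclamped) predicted Hb mass in mg: b0 + sum(bi * xi)."""
    return float(coeffs.b0 + coeffs.as_array()[1:] @ x.as_array())


def clamp_mass(mass: float) -> float:
    """Reported masses are non-negative; evaluation uses the raw value."""
    return max(0.0, float(mass))
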