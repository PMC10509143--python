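"""Color-moment features for Hb mass regression.

Four predictors summarize a cropped sponge image: the first three color
moments of the pixel intensity distribution — mean (MEA), root-mean-square
deviation (VAR) and the signed cube root of the third central moment
(SKE) — and the area ratio of the blood-stained region to the whole
sponge crop. MEA tracks overall darkening by hemoglobin, VAR the spread
of the color distribution, SKE its asymmetry, and the area ratio the
stained footprint, which scales with applied volume.

Moments are computed per channel on the [0, 1] intensity scale and
averaged across channels to yield the scalars X1-X3. By default they are
taken over the whole crop: the whole-crop mean mixes stain darkness with
stain extent and therefore carries the concentration x volume interaction
that the Hb mass (their product) consists of, keeping the linear model's
job nearly linear. Moments restricted to the segmented blood region are
available via ``region="blood"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ColorMoments",
    "FeatureVector",
    "segment_blood",
    "color_moments",
    "extract_features",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("x1", "x2", "x3", "x4")

#: Euclidean RGB distance from the sponge base color above which a pixel
#: can be blood (combined with red-channel dominance).
BLOOD_COLOR_THRESHOLD = 30.0 / 255.0


@dataclass(frozen=True)
class ColorMoments:
    """First three color moments of an intensity sample (population norm)."""

    mea: float
    var: float
    ske: float


@dataclass(frozen=True)
class FeatureVector:
    """The four predictors X1=MEA, X2=VAR, X3=SKE, X4=area ratio."""

    x1: float
    x2: float
    x3: float
    x4: float

    def __post_init__(self) -> None:
        vals = (self.x1, self.x2, self.x3, self.x4)
        if not all(np.isfinite(vals)):
            raise ValueError(f"features must be finite, got {vals}")
        if not 0.0 <= self.x4 <= 1.0:
            raise ValueError(f"area ratio x4 must lie in [0, 1], got {self.x4}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3, self.x4], dtype=np.float64)


def _to_unit_rgb(crop: np.ndarray) -> np.ndarray:
    crop = np.asarray(crop)
    if crop.ndim != 3 or crop.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB crop, got shape {crop.shape}")
    if crop.dtype == np.uint8:
        return crop.astype(np.float64) / 255.0
    crop = crop.astype(np.float64)
    return crop / 255.0 if crop.max(initial=0.0) > 1.0 else crop


def segment_blood(
    crop: np.ndarray,
    sponge_base_color: Sequence[float],
    *,
    threshold: float = BLOOD_COLOR_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of blood-stained pixels in a sponge crop.

    A pixel is blood iff its color is far from the clean sponge color
    (Euclidean RGB distance > ``threshold`` on the [0, 1] scale) *and*
    its red channel dominates green and blue — hemoglobin absorbs far
    less in red, so stains stay red-brown while e.g. shadows do not.
    """
    rgb = _to_unit_rgb(crop)
    base = np.asarray(sponge_base_color, dtype=np.float64).reshape(1, 1, 3)
    dist = np.sqrt(((rgb - base) ** 2).sum(axis=2))
    red_dominant = (rgb[..., 0] > rgb[..., 1]) & (rgb[..., 0] > rgb[..., 2])
    return (dist > threshold) & red_dominant


def color_moments(values: Sequence[float] | np.ndarray) -> ColorMoments:
    """MEA / VAR / SKE of a 1-D intensity sample on the [0, 1] scale.

    All three use population normalization (divisor N):
    MEA = mean, VAR = sqrt(mean((v - MEA)^2)),
    SKE = cbrt(mean((v - MEA)^3)) with the sign preserved.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("color_moments requires at least one value")
    mea = v.mean()
    dev = v - mea
    var = float(np.sqrt(np.mean(dev**2)))
    ske = float(np.cbrt(np.mean(dev**3)))
    return ColorMoments(mea=float(mea), var=var, ske=ske)


def extract_features(
    crop: np.ndarray,
    sponge_base_color: Sequence[float],
    *,
    region: str = "crop",
    threshold: float = BLOOD_COLOR_THRESHOLD,
) -> FeatureVector:
    """Compute the four predictors from a cropped sponge image.

    ``region="crop"`` (default) computes the moments over all crop
    pixels; ``region="blood"`` restricts them to the segmented blood
    mask, falling back to the whole crop when the mask is empty so that
    clean sponges remain predictable. Either way, per-channel moments are
    averaged across R, G, B, and ``x4`` is the blood-pixel fraction.
    """
    if region not in ("crop", "blood"):
        raise ValueError(f"region must be 'crop' or 'blood', got {region!r}")
    rgb = _to_unit_rgb(crop)
    if rgb.size == 0:
        raise ValueError("empty crop")
    mask = segment_blood(crop, sponge_base_color, threshold=threshold)
    x4 = float(mask.mean())

    if region == "blood" and mask.any():
        pixels = rgb[mask]  # (n_blood, 3)
    else:
        pixels = rgb.reshape(-1, 3)

    moments = [color_moments(pixels[:, c]) for c in range(3)]
    return FeatureVector(
        x1=float(np.mean([m.mea for m in moments])),
        x2=float(np.mean([m.var for m in moments])),
        x3=float(np.mean([m.ske for m in moments])),
        x4=x4,
    )
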