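"""Synthetic blood-soaked sponge scenes with exact hemoglobin ground truth.

Real intraoperative sponge photographs with reference Hb masses are not
publicly deposited, so every downstream stage of this package is exercised
against rendered scenes in which the true Hb mass, the sponge box and the
stain footprint are known exactly.

The forward color model is a Beer-Lambert-style per-channel attenuation.
A blood sample of concentration ``c`` (g/L) and volume ``v`` (mL) spreads
over a stain of area ``v / a`` cm^2, where ``a`` is the sponge's
absorbency (mL of blood held per cm^2 of stain). The Hb surface density is
therefore

    sigma = hb_mass / stain_area = (c * v) / (v / a) = c * a   [mg/cm^2]

independent of volume, and each channel of the stained sponge is darkened
by ``exp(-k_c * sigma)`` with per-channel absorption coefficients
``k_R << k_G ~ k_B`` so stains render red-brown. Stain *area* is
proportional to volume while stain *darkness* is monotone in
concentration: the area ratio carries volume information and the color
statistics carry concentration information, mirroring the predictors the
estimation method relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .roi import Annotation, BoundingBox, write_annotation

__all__ = [
    "BloodSample",
    "SceneParams",
    "SyntheticImage",
    "make_blood_sample",
    "render_sponge_image",
    "generate_dataset",
    "MANIFEST_COLUMNS",
    "DEFAULT_CONCENTRATION_RANGE",
    "DEFAULT_VOLUME_RANGE",
]

#: Clinical range of Hb concentrations emulated by the default generator.
DEFAULT_CONCENTRATION_RANGE = (50.0, 170.0)

#: Default applied blood volume range (mL). Together with the
#: concentration range this spans Hb masses of 10-510 mg per sponge.
DEFAULT_VOLUME_RANGE = (0.2, 3.0)

MANIFEST_COLUMNS = ["filename", "concentration_g_per_L", "volume_mL", "hb_mass_mg", "seed"]


@dataclass(frozen=True)
class BloodSample:
    """One sponge's blood load.

    ``hb_mass`` (mg) is always exactly ``concentration * volume``
    (g/L x mL = mg) and is computed, never supplied.
    """

    concentration: float  # g/L
    volume: float  # mL
    hb_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError(
                f"concentration must be positive (g/L); got {self.concentration}. "
                "Hb mass is concentration (g/L) x volume (mL) in mg."
            )
        if self.volume < 0:
            raise ValueError(
                f"volume must be non-negative (mL); got {self.volume}. "
                "Hb mass is concentration (g/L) x volume (mL) in mg."
            )
        object.__setattr__(self, "hb_mass", self.concentration * self.volume)


def make_blood_sample(concentration: float, volume: float) -> BloodSample:
    """Create a :class:`BloodSample`; ``hb_mass = concentration * volume`` mg."""
    return BloodSample(concentration=float(concentration), volume=float(volume))


@dataclass(frozen=True)
class SceneParams:
    """Geometry, optics and noise of one rendered sponge scene.

    Defaults model a 10x10 cm surgical sponge photographed at 40 px/cm on
    a green drape background. ``absorption_coefficients`` are per-channel
    Beer-Lambert constants in cm^2/mg; ``absorbency_ml_per_cm2`` converts
    applied volume to stain area.
    """

    image_height: int = 512
    image_width: int = 512
    sponge_box: BoundingBox = BoundingBox(50, 450, 100, 500)
    sponge_base_color: tuple[float, float, float] = (0.93, 0.91, 0.86)
    background_color: tuple[float, float, float] = (0.20, 0.35, 0.30)
    absorption_coefficients: tuple[float, float, float] = (0.030, 0.145, 0.125)
    absorbency_ml_per_cm2: float = 0.04
    pixels_per_cm: float = 40.0
    stain_center_jitter: float = 0.15  # fraction of sponge size
    stain_roughness: float = 0.12  # relative boundary perturbation
    stain_harmonics: int = 6
    noise_sd: float = 2.0  # additive Gaussian noise SD, 0-255 scale
    texture_amp: float = 0.02  # multiplicative sponge texture amplitude

    def __post_init__(self) -> None:
        if self.sponge_box.row_end > self.image_height or self.sponge_box.col_end > self.image_width:
            raise ValueError("sponge_box must lie within the image frame")
        if any(k <= 0 for k in self.absorption_coefficients):
            raise ValueError("absorption coefficients must be strictly positive")
        kr, kg, kb = self.absorption_coefficients
        if not (kr < kg and kr < kb):
            raise ValueError("red must attenuate least (k_R < k_G and k_R < k_B)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.absorbency_ml_per_cm2 <= 0 or self.pixels_per_cm <= 0:
            raise ValueError("absorbency and pixel scale must be positive")

    def scaled(self, size: int) -> "SceneParams":
        """Same physical scene rendered at ``size`` x ``size`` pixels.

        The camera scale shrinks with the frame so surface densities, and
        hence stain colors, are unchanged.
        """
        f = size / self.image_height
        box = BoundingBox(
            int(round(self.sponge_box.row_start * f)),
            int(round(self.sponge_box.row_end * f)),
            int(round(self.sponge_box.col_start * f)),
            int(round(self.sponge_box.col_end * f)),
        )
        return replace(
            self,
            image_height=size,
            image_width=size,
            sponge_box=box,
            pixels_per_cm=self.pixels_per_cm * f,
        )


@dataclass(frozen=True)
class SyntheticImage:
    """A rendered scene plus its full ground truth."""

    pixels: np.ndarray  # HxWx3 uint8
    sample: BloodSample
    truth_sponge_box: BoundingBox
    truth_stain_mask: np.ndarray  # HxW bool
    seed: int


def _stain_mask(
    scene: SceneParams, sample: BloodSample, rng: np.random.Generator
) -> np.ndarray:
    """Irregular stain footprint, clipped to the sponge box.

    The boundary is a circle of the area implied by the sample's volume,
    perturbed by a low-order random Fourier series in the polar angle.
    """
    box = scene.sponge_box
    mask = np.zeros((scene.image_height, scene.image_width), dtype=bool)
    if sample.volume == 0:
        return mask

    area_cm2 = sample.volume / scene.absorbency_ml_per_cm2
    radius_px = math.sqrt(area_cm2 / math.pi) * scene.pixels_per_cm

    jitter_r = scene.stain_center_jitter * box.height
    jitter_c = scene.stain_center_jitter * box.width
    center_r = (box.row_start + box.row_end) / 2 + rng.uniform(-jitter_r, jitter_r)
    center_c = (box.col_start + box.col_end) / 2 + rng.uniform(-jitter_c, jitter_c)

    m = np.arange(1, scene.stain_harmonics + 1)
    a = rng.standard_normal(scene.stain_harmonics) / m
    b = rng.standard_normal(scene.stain_harmonics) / m

    rr = np.arange(box.row_start, box.row_end, dtype=np.float64)[:, None] - center_r
    cc = np.arange(box.col_start, box.col_end, dtype=np.float64)[None, :] - center_c
    rho = np.hypot(rr, cc)
    theta = np.arctan2(rr, cc)
    perturb = np.zeros_like(theta)
    for k in range(scene.stain_harmonics):
        perturb += a[k] * np.cos((k + 1) * theta) + b[k] * np.sin((k + 1) * theta)
    boundary = radius_px * np.clip(1.0 + scene.stain_roughness * perturb, 0.2, None)
    mask[box.row_start : box.row_end, box.col_start : box.col_end] = rho <= boundary
    return mask


def render_sponge_image(
    sample: BloodSample, scene: SceneParams, seed: int
) -> SyntheticImage:
    """Render one 8-bit RGB sponge scene with ground truth.

    Rendering is bit-exact under a fixed ``(sample, scene, seed)`` triple.
    The stain footprint never raises when it overflows the sponge — it is
    clipped to the sponge box, and ``truth_stain_mask`` records the
    clipped footprint.
    """
    rng = np.random.default_rng(seed)
    h, w = scene.image_height, scene.image_width
    box = scene.sponge_box

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(scene.background_color)

    # gray multiplicative texture, shared across channels
    texture = 1.0 + scene.texture_amp * rng.standard_normal((box.height, box.width))
    sponge = np.asarray(scene.sponge_base_color)[None, None, :] * texture[:, :, None]

    stain = _stain_mask(scene, sample, rng)
    if stain.any():
        sigma = sample.concentration * scene.absorbency_ml_per_cm2  # mg/cm^2
        attenuation = np.exp(-np.asarray(scene.absorption_coefficients) * sigma)
        local = stain[box.row_start : box.row_end, box.col_start : box.col_end]
        sponge[local] *= attenuation

    img[box.row_start : box.row_end, box.col_start : box.col_end] = sponge

    img *= 255.0
    if scene.noise_sd > 0:
        img += rng.normal(0.0, scene.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    return SyntheticImage(
        pixels=pixels,
        sample=sample,
        truth_sponge_box=box,
        truth_stain_mask=stain,
        seed=int(seed),
    )


def generate_dataset(
    n: int,
    out_dir: str | Path,
    *,
    concentration_range: Sequence[float] = DEFAULT_CONCENTRATION_RANGE,
    volume_range: Sequence[float] = DEFAULT_VOLUME_RANGE,
    scene: SceneParams | None = None,
    seed: int = 0,
    write_annotations: bool = False,
    prefix: str = "sponge",
) -> pd.DataFrame:
    """Render ``n`` sponge scenes and write PNGs plus a CSV manifest.

    Concentrations are drawn uniformly from ``concentration_range``
    (default 50-170 g/L) and volumes from ``volume_range``. A single
    master ``seed`` fans out into one seed per image (via
    ``numpy.random.SeedSequence``), recorded in the manifest so every
    image is independently reproducible. With ``write_annotations`` a
    VOC XML file recording the true sponge box accompanies each PNG.

    Returns the manifest as a DataFrame; also written to
    ``out_dir/manifest.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo_c, hi_c = concentration_range
    lo_v, hi_v = volume_range
    if lo_c <= 0 or lo_v < 0 or hi_c < lo_c or hi_v < lo_v:
        raise ValueError("invalid concentration or volume range")
    scene = scene if scene is not None else SceneParams()

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    image_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root_ss.spawn(n)]

    concentrations = rng.uniform(lo_c, hi_c, size=n)
    volumes = rng.uniform(lo_v, hi_v, size=n)

    digits = max(4, len(str(n - 1)))
    rows = []
    for i in range(n):
        sample = make_blood_sample(concentrations[i], volumes[i])
        image = render_sponge_image(sample, scene, image_seeds[i])
        filename = f"{prefix}_{i:0{digits}d}.png"
        iio.imwrite(out_dir / filename, image.pixels)
        if write_annotations:
            ann = Annotation(
                image_filename=filename,
                boxes=[("sponge", image.truth_sponge_box)],
                image_size=(scene.image_height, scene.image_width),
            )
            write_annotation(ann, out_dir / f"{prefix}_{i:0{digits}d}.xml")
        rows.append(
            {
                "filename": filename,
                "concentration_g_per_L": sample.concentration,
                "volume_mL": sample.volume,
                "hb_mass_mg": sample.hb_mass,
                "seed": image_seeds[i],
            }
        )

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
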