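import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from spongehb import synthetic as syn
from spongehb import roi


@pytest.fixture(scope="session")
def small_scene():
    """Default physical scene rendered at 96x96 px (fast), camera noise on."""
    return syn.SceneParams().scaled(96)


@pytest.fixture(scope="session")
def quiet_scene(small_scene):
    """Same scene with camera noise off (for exact colorimetry checks)."""
    return dataclasses.replace(small_scene, noise_sd=0.0)


@pytest.fixture(scope="session")
def rendered_batch(small_scene):
    """50 default-scene renders with ground truth, shared across tests."""
    rng = np.random.default_rng(2024)
    images = []
    for i in range(50):
        sample = syn.make_blood_sample(rng.uniform(50, 170), rng.uniform(0.2, 3.0))
        images.append(syn.render_sponge_image(sample, small_scene, 9000 + i))
    return images


@pytest.fixture(scope="session")
def crops_with_masses(quiet_scene):
    """Noise-free detected crops + true masses, for feature/linear tests."""
    rng = np.random.default_rng(7)
    crops, masses = [], []
    for i in range(60):
        sample = syn.make_blood_sample(rng.uniform(50, 170), rng.uniform(0.2, 3.0))
        img = syn.render_sponge_image(sample, quiet_scene, 4000 + i)
        box = roi.detect_sponge_region(img.pixels, quiet_scene.background_color)
        crops.append(roi.crop(img.pixels, box))
        masses.append(sample.hb_mass)
    return crops, np.array(masses)
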