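"""Color moments and blood segmentation against brute-force oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spongehb import features as F
from spongehb import roi, synthetic as syn

BASE = (0.93, 0.91, 0.86)


def moments_oracle(values):
    """Elementwise loop implementation of MEA / VAR / SKE."""
    n = len(values)
    mea = sum(values) / n
    var = math.sqrt(sum((v - mea) ** 2 for v in values) / n)
    third = sum((v - mea) ** 3 for v in values) / n
    ske = math.copysign(abs(third) ** (1 / 3), third)
    return mea, var, ske


class TestColorMoments:
    def test_constant_input_has_zero_spread_and_skew(self):
        m = F.color_moments([0.42] * 7)
        assert (m.mea, m.var, m.ske) == (pytest.approx(0.42), 0.0, 0.0)

    def test_two_point_sample(self):
        m = F.color_moments([0.0, 1.0])
        assert m.mea == 0.5 and m.var == 0.5 and m.ske == pytest.approx(0.0)

    def test_hand_computed_three_point_sample(self):
        m = F.color_moments([0.0, 0.0, 1.0])
        assert m.mea == pytest.approx(1 / 3)
        assert m.var == pytest.approx(math.sqrt(2) / 3)
        assert m.ske == pytest.approx((2 / 27) ** (1 / 3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            F.color_moments([])

    @given(
        arrays(np.float64, st.integers(1, 40),
               elements=st.floats(0, 1, allow_nan=False))
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_loop_oracle(self, values):
        m = F.color_moments(values)
        mea, var, ske = moments_oracle(list(values))
        assert m.mea == pytest.approx(mea, abs=1e-12)
        assert m.var == pytest.approx(var, abs=1e-12)
        assert m.ske == pytest.approx(ske, abs=1e-12)

    @given(
        arrays(np.float64, st.integers(2, 30),
               elements=st.floats(0.01, 1, allow_nan=False)),
        st.floats(0.1, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, values, c):
        m1 = F.color_moments(values)
        m2 = F.color_moments(values * c)
        assert m2.mea == pytest.approx(c * m1.mea, rel=1e-9, abs=1e-12)
        assert m2.var == pytest.approx(c * m1.var, rel=1e-9, abs=1e-12)
        # the cube root amplifies rounding error near zero skew
        assert m2.ske == pytest.approx(c * m1.ske, rel=1e-9, abs=1e-5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 100)
        m1, m2 = F.color_moments(v), F.color_moments(rng.permutation(v))
        assert m1.mea == pytest.approx(m2.mea, abs=1e-12)
        assert m1.var == pytest.approx(m2.var, abs=1e-12)
        assert m1.ske == pytest.approx(m2.ske, abs=1e-12)


class TestSegmentBlood:
    def test_clean_sponge_has_empty_mask(self):
        crop = np.full((20, 20, 3), np.asarray(BASE) * 255, dtype=np.uint8).reshape(20, 20, 3)
        assert F.segment_blood(crop, BASE).mean() <= 0.01

    def test_fully_stained_crop_is_all_blood(self):
        crop = np.full((20, 20, 3), 0, dtype=np.uint8)
        crop[..., 0], crop[..., 1], crop[..., 2] = 140, 60, 60
        assert F.segment_blood(crop, BASE).mean() >= 0.99

    def test_mask_fraction_matches_truth_area(self, quiet_scene):
        """On a noise-free render whose stain covers ~25% of the sponge,
        the segmented fraction agrees with the footprint within 0.02."""
        # stain fraction = (v / a) * ppc^2 / sponge_area; solve v for 0.25
        box = quiet_scene.sponge_box
        target = 0.25 * box.area / quiet_scene.pixels_per_cm**2  # cm^2
        vol = target * quiet_scene.absorbency_ml_per_cm2
        img = syn.render_sponge_image(
            syn.make_blood_sample(110, vol), quiet_scene, 31
        )
        crop = roi.crop(img.pixels, box)
        truth_frac = img.truth_stain_mask.sum() / box.area
        seg_frac = F.segment_blood(crop, quiet_scene.sponge_base_color).mean()
        assert seg_frac == pytest.approx(truth_frac, abs=0.02)


class TestExtractFeatures:
    def test_constant_clean_crop(self):
        v = 0.7
        crop = np.full((10, 10, 3), v, dtype=np.float64)
        fv = F.extract_features(crop, BASE)
        assert fv.x1 == pytest.approx(v)
        assert fv.x2 == pytest.approx(0.0)
        assert fv.x3 == pytest.approx(0.0)
        assert fv.x4 <= 0.01

    def test_fully_stained_crop_area_ratio(self):
        crop = np.zeros((10, 10, 3))
        crop[..., 0], crop[..., 1], crop[..., 2] = 0.55, 0.2, 0.2
        assert F.extract_features(crop, BASE).x4 >= 0.99

    def test_features_bounded_and_finite(self, crops_with_masses):
        for crop in crops_with_masses[0][:10]:
            fv = F.extract_features(crop, BASE)
            assert 0.0 <= fv.x4 <= 1.0
            assert np.isfinite(fv.as_array()).all()

    @pytest.mark.parametrize("region", ["crop", "blood"])
    def test_x1_decreases_with_concentration(self, quiet_scene, region):
        """Darker stains at higher Hb concentration pull MEA down, for
        both whole-crop and blood-region moment conventions."""
        x1s = []
        for conc in (50, 90, 130, 170):
            img = syn.render_sponge_image(
                syn.make_blood_sample(conc, 1.5), quiet_scene, 13
            )
            crop = roi.crop(img.pixels, img.truth_sponge_box)
            x1s.append(
                F.extract_features(
                    crop, quiet_scene.sponge_base_color, region=region
                ).x1
            )
        assert all(a > b for a, b in zip(x1s, x1s[1:]))

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="region"):
            F.extract_features(np.zeros((4, 4, 3)), BASE, region="sponge")
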