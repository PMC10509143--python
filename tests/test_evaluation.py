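"""Metric formulas and Bland-Altman agreement, against loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongehb import evaluation as E


def mae_oracle(a, p):
    return sum(abs(pi - ai) for ai, pi in zip(a, p)) / len(a)


def mape_oracle(a, p):
    return 100 * sum(abs((pi - ai) / ai) for ai, pi in zip(a, p)) / len(a)


def r2_oracle(a, p):
    ybar = sum(a) / len(a)
    return 1 - sum((ai - pi) ** 2 for ai, pi in zip(a, p)) / sum(
        (ai - ybar) ** 2 for ai in a
    )


class TestMetricFormulas:
    def test_perfect_prediction(self):
        y = [10.0, 20.0, 30.0]
        assert E.mae(y, y) == 0.0
        assert E.mape(y, y) == 0.0
        assert E.r2(y, y) == 1.0

    def test_worked_examples(self):
        assert E.mae([0.0, 2.0], [1.0, 1.0]) == 1.0
        assert E.mape([100.0], [90.0]) == pytest.approx(10.0)

    def test_mae_shift_property(self):
        y = np.array([5.0, 9.0, 14.0])
        assert E.mae(y, y + 3.7) == pytest.approx(3.7)

    def test_mape_zero_actual_raises_with_index(self):
        with pytest.raises(ZeroDivisionError, match="index 1"):
            E.mape([5.0, 0.0, 2.0], [5.0, 1.0, 2.0])

    def test_r2_of_mean_predictor_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert E.r2(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_r2_negative_for_worse_than_mean(self):
        y = np.array([1.0, 2.0, 3.0])
        assert E.r2(y, np.array([3.0, 1.0, -2.0])) < 0.0

    def test_r2_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            E.r2([2.0, 2.0], [1.0, 3.0])

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            E.mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            E.mae([], [])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_metrics_match_loop_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        a = rng.uniform(1, 500, n)
        p = a + rng.normal(0, 20, n)
        assert E.mae(a, p) == pytest.approx(mae_oracle(a, p), abs=1e-12)
        assert E.mape(a, p) == pytest.approx(mape_oracle(a, p), abs=1e-10)
        if np.ptp(a) > 0:
            assert E.r2(a, p) == pytest.approx(r2_oracle(a, p), abs=1e-10)


class TestBlandAltman:
    def test_constant_differences_degenerate(self):
        a = np.array([10.0, 20.0, 30.0])
        rep = E.bland_altman(a + 2.5, a)
        assert rep.bias == pytest.approx(2.5)
        assert rep.sd_diff == 0.0
        assert rep.loa_lower == rep.loa_upper == pytest.approx(2.5)

    def test_symmetry_identity(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(10, 500, 100)
        p = a + rng.normal(2, 15, 100)
        rep = E.bland_altman(p, a)
        assert rep.loa_lower + rep.loa_upper == pytest.approx(2 * rep.bias, abs=1e-9)

    def test_monte_carlo_recovery_of_known_normal(self):
        """10,000 differences ~ N(5, 10^2): bias near 5, LOA near
        (-14.6, 24.6)."""
        rng = np.random.default_rng(123)
        a = rng.uniform(50, 500, 10_000)
        p = a + rng.normal(5.0, 10.0, 10_000)
        rep = E.bland_altman(p, a)
        assert rep.bias == pytest.approx(5.0, abs=0.3)
        assert rep.loa_lower == pytest.approx(-14.6, abs=0.5)
        assert rep.loa_upper == pytest.approx(24.6, abs=0.5)

    def test_matched_ci_halfwidths_equal_for_bias_and_loa(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(10, 100, 50)
        p = a + rng.normal(0, 5, 50)
        rep = E.bland_altman(p, a, loa_ci="matched")
        hw = lambda ci, point: (ci[1] - ci[0]) / 2  # noqa: E731
        assert hw(rep.ci_bias, rep.bias) == pytest.approx(
            hw(rep.ci_loa_lower, rep.loa_lower)
        )
        assert hw(rep.ci_bias, rep.bias) == pytest.approx(
            1.96 * rep.sd_diff / np.sqrt(rep.n)
        )

    def test_textbook_loa_ci_wider_than_matched(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(10, 100, 50)
        p = a + rng.normal(0, 5, 50)
        matched = E.bland_altman(p, a, loa_ci="matched")
        textbook = E.bland_altman(p, a, loa_ci="textbook")
        assert (textbook.ci_loa_upper[1] - textbook.ci_loa_upper[0]) > (
            matched.ci_loa_upper[1] - matched.ci_loa_upper[0]
        )

    def test_percentile_mode_converges_to_parametric_for_normal_data(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(10, 500, 20_000)
        p = a + rng.normal(5.0, 10.0, 20_000)
        par = E.bland_altman(p, a, mode="parametric")
        non = E.bland_altman(p, a, mode="percentile")
        assert non.loa_lower == pytest.approx(par.loa_lower, abs=0.6)
        assert non.loa_upper == pytest.approx(par.loa_upper, abs=0.6)

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(10, 100, 40)
        p = a + rng.normal(1, 4, 40)
        r1 = E.bland_altman(p, a)
        r2_ = E.bland_altman(p + 100, a + 100)
        assert r1.bias == pytest.approx(r2_.bias)
        assert r1.loa_lower == pytest.approx(r2_.loa_lower)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            E.bland_altman([1.0, 2.0], [1.0, 2.0])


class TestCompareModels:
    def test_self_comparison_is_zero(self):
        m = {"a": E.MetricSet(10, 5, 0.9), "b": E.MetricSet(10, 5, 0.9)}
        table = E.compare_models(m)
        row = table[(table.baseline == "a") & (table.candidate == "b")].iloc[0]
        assert row.mae_improvement_mg == 0.0
        assert row.r2_improvement == 0.0

    def test_improvement_signs(self):
        m = {
            "worse": E.MetricSet(mae=20.0, mape=15.0, r2=0.90),
            "better": E.MetricSet(mae=12.0, mape=9.0, r2=0.97),
        }
        table = E.compare_models(m)
        row = table[(table.baseline == "worse") & (table.candidate == "better")].iloc[0]
        assert row.mae_improvement_mg == pytest.approx(8.0)
        assert row.mape_improvement_pct == pytest.approx(6.0)
        assert row.r2_improvement == pytest.approx(0.07)

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            E.compare_models({"only": E.MetricSet(1, 1, 1)})


def test_bland_altman_plot_writes_file(tmp_path):
    rng = np.random.default_rng(5)
    a = rng.uniform(10, 100, 30)
    p = a + rng.normal(0, 5, 30)
    out = tmp_path / "ba.png"
    E.bland_altman_plot(p, a, out)
    assert out.stat().st_size > 0
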