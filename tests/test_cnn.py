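"""CNN regressors: shape contracts, SE-block behavior, training loop."""

import numpy as np
import pytest

from spongehb.nn import (
    RegressorConfig,
    TrainingDivergedError,
    build_regressor,
    composite_loss,
    kfold_cv,
    kfold_indices,
    load_regressor,
    predict_mass,
    predict_masses,
    save_regressor,
    train_regressor,
)
from spongehb.nn.resnet import Bottleneck, SEBlock


@pytest.fixture(scope="module")
def tiny32():
    return RegressorConfig.tiny(seed=3, input_size=32, epochs=4)


@pytest.fixture(scope="module")
def small_training_set(crops_with_masses):
    crops, masses = crops_with_masses
    return crops[:32], masses[:32]


class TestBuildAndShapes:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            build_regressor("densenet", RegressorConfig.tiny())

    @pytest.mark.parametrize("kind", ["resnet", "se_resnet"])
    def test_tiny_variant_maps_batch_to_scalars(self, kind):
        cfg = RegressorConfig.tiny(seed=0)
        model = build_regressor(kind, cfg)
        x = np.random.default_rng(0).standard_normal((3, 3, 64, 64))
        out = model.forward(x)
        assert out.shape == (3,)
        assert np.isfinite(out).all()

    def test_tiny_variant_is_small(self):
        model = build_regressor("se_resnet", RegressorConfig.tiny())
        assert model.num_parameters() <= 200_000

    @pytest.mark.parametrize("kind", ["resnet", "se_resnet"])
    def test_full_50_layer_variant_forward_at_224(self, kind):
        cfg = RegressorConfig(seed=0)
        model = build_regressor(kind, cfg)
        x = np.random.default_rng(1).standard_normal((2, 3, 224, 224))
        out = model.forward(x)
        assert out.shape == (2,)
        assert np.isfinite(out).all()
        if kind == "se_resnet":
            # one SE block per bottleneck; reduction 1/8 everywhere
            assert all(se.hidden == se.channels // 8 for se in model.se_blocks())
            assert len(model.se_blocks()) == 3 + 4 + 6 + 3

    def test_se_reduction_must_divide_channels(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="divide"):
            SEBlock(10, 4, rng)


class TestSEBlock:
    def setup_method(self):
        self.rng = np.random.default_rng(42)
        self.se = SEBlock(8, 4, self.rng)
        self.x = self.rng.standard_normal((2, 8, 5, 5))

    def test_squeeze_of_constant_channels_returns_constants(self):
        consts = np.arange(8, dtype=float)
        x = np.broadcast_to(consts[None, :, None, None], (1, 8, 4, 4)).copy()
        np.testing.assert_allclose(self.se.squeeze(x), consts[None, :])

    def test_gates_strictly_inside_unit_interval(self):
        g = self.se.gates(self.x)
        assert (g > 0).all() and (g < 1).all()
        out = self.se.forward(self.x, train=False)
        assert (np.abs(out) <= np.abs(self.x)).all()

    def test_forced_unit_gates_give_identity(self):
        self.se.w2.value[...] = 0.0
        self.se.b2.value[...] = 500.0  # sigmoid(500) == 1.0 in float64
        np.testing.assert_array_equal(self.se.forward(self.x, train=False), self.x)

    def test_zeroed_excitation_halves_every_channel(self):
        """SE identity limit: zero weights and zero bias give gates of
        exactly sigmoid(0) = 1/2, so the block scales the map by 0.5."""
        self.se.w1.value[...] = 0.0
        self.se.b1.value[...] = 0.0
        self.se.w2.value[...] = 0.0
        self.se.b2.value[...] = 0.0
        np.testing.assert_array_equal(self.se.forward(self.x, train=False), 0.5 * self.x)

    def test_se_sits_before_residual_addition(self):
        """With unit gates the SE bottleneck reduces to the plain one."""
        rng = np.random.default_rng(0)
        plain = Bottleneck(4, 2, 8, stride=1, se_reduction=None, rng=np.random.default_rng(5))
        gated = Bottleneck(4, 2, 8, stride=1, se_reduction=4, rng=np.random.default_rng(5))
        # same draw order up to the SE params; copy weights to be safe
        for p_src, p_dst in zip(plain.params(), [p for p in gated.params() if not p.name.startswith("se.")]):
            p_dst.value[...] = p_src.value
        gated.se.w2.value[...] = 0.0
        gated.se.b2.value[...] = 500.0
        x = rng.standard_normal((2, 4, 6, 6))
        np.testing.assert_allclose(
            gated.forward(x, train=False), plain.forward(x, train=False)
        )


class TestLoss:
    def test_composite_loss_equals_mse_plus_l1(self):
        rng = np.random.default_rng(0)
        pred, target = rng.standard_normal(64), rng.standard_normal(64)
        for lam in (0.0, 0.5, 1.0):
            loss, _ = composite_loss(pred, target, lam)
            mse = np.mean((pred - target) ** 2)
            l1 = np.mean(np.abs(pred - target))
            assert loss == pytest.approx(mse + lam * l1, abs=1e-6)

    def test_loss_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        pred, target = rng.standard_normal(10), rng.standard_normal(10)
        _, grad = composite_loss(pred, target, 1.0)
        eps = 1e-6
        for i in range(10):
            pp, pm = pred.copy(), pred.copy()
            pp[i] += eps
            pm[i] -= eps
            num = (composite_loss(pp, target, 1.0)[0] - composite_loss(pm, target, 1.0)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)


class TestTraining:
    def test_loss_decreases_and_history_recorded(self, tiny32, small_training_set):
        crops, masses = small_training_set
        model = build_regressor("se_resnet", tiny32)
        train_regressor(model, crops, masses, tiny32)
        assert len(model.history) == tiny32.epochs
        assert model.history[-1] < model.history[0]
        assert model.trained

    def test_same_seed_reproduces_loss_history(self, tiny32, small_training_set):
        crops, masses = small_training_set
        h = []
        for _ in range(2):
            model = build_regressor("resnet", tiny32)
            train_regressor(model, crops, masses, tiny32)
            h.append(model.history)
        assert h[0] == h[1]

    def test_empty_dataset_rejected(self, tiny32):
        model = build_regressor("resnet", tiny32)
        with pytest.raises(ValueError, match="empty"):
            train_regressor(model, [], [], tiny32)

    def test_untrained_model_refuses_to_predict(self, tiny32, small_training_set):
        model = build_regressor("resnet", tiny32)
        with pytest.raises(RuntimeError, match="untrained"):
            predict_mass(model, small_training_set[0][0])

    def test_prediction_contract(self, tiny32, small_training_set):
        crops, masses = small_training_set
        model = build_regressor("se_resnet", tiny32)
        train_regressor(model, crops, masses, tiny32)
        # pure function at inference: identical crops, identical outputs
        a = predict_masses(model, [crops[0], crops[1], crops[0]])
        assert a[0] == a[2]
        assert np.isfinite(a).all()
        # order preserved vs one-at-a-time, clamped scalar version >= 0
        singles = [predict_masses(model, [c])[0] for c in crops[:3]]
        np.testing.assert_allclose(predict_masses(model, crops[:3]), singles)
        assert predict_mass(model, crops[0]) >= 0.0

    def test_save_load_roundtrip(self, tiny32, small_training_set, tmp_path):
        crops, masses = small_training_set
        model = build_regressor("se_resnet", tiny32)
        train_regressor(model, crops, masses, tiny32)
        save_regressor(model, tmp_path / "m.npz")
        loaded = load_regressor(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            predict_masses(model, crops[:4]), predict_masses(loaded, crops[:4])
        )
        assert loaded.history == model.history


class TestKFold:
    def test_595_records_give_five_folds_of_119(self):
        folds = kfold_indices(595, 5, seed=0)
        assert [len(f) for f in folds] == [119] * 5

    def test_unbalanced_fold_sizes_differ_by_at_most_one(self):
        folds = kfold_indices(11, 5, seed=0)
        assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 3]

    def test_folds_partition_the_dataset(self):
        folds = kfold_indices(37, 5, seed=1)
        joined = np.concatenate(folds)
        assert len(joined) == 37
        assert len(np.unique(joined)) == 37

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_indices(3, 5, seed=0)

    def test_kfold_cv_returns_k_reports(self, crops_with_masses):
        crops, masses = crops_with_masses
        cfg = RegressorConfig.tiny(seed=0, input_size=32, epochs=2)
        result = kfold_cv(crops[:15], masses[:15], kind="resnet", config=cfg, k=3, seed=0)
        assert len(result["folds"]) == 3
        assert len(result["agreement"]) == 3
        assert np.isfinite(result["mean"].mae)
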