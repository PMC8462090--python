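"""Residual-network construction, training behaviour and prediction
contracts."""

import numpy as np
import pytest

from berryspec.models import (
    ModelConfig,
    TrainingError,
    build_resnet_1d,
    build_resnet_3d,
    load_model,
    predict,
    save_model,
    train,
)


def _cls_config(**kw):
    base = dict(task="classification", n_bands=40, epochs=50, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestArchitecture:
    def test_classification_head_outputs_four(self, rng):
        net = build_resnet_1d(_cls_config())
        out = net.forward(rng.normal(size=(3, 1, 40)), train=False)
        assert out.shape == (3, 4)

    def test_regression_head_outputs_one(self, rng):
        net = build_resnet_1d(_cls_config(task="regression"))
        out = net.forward(rng.normal(size=(3, 1, 40)), train=False)
        assert out.shape == (3, 1)

    def test_zero_input_forward_is_finite(self):
        net = build_resnet_1d(_cls_config())
        out = net.forward(np.zeros((2, 1, 40)), train=False)
        assert np.all(np.isfinite(out))

    def test_parameter_count_matches_hand_tally_1d(self):
        # stem conv 1x16x7 + stem BN; three bottleneck stages with widths
        # (16, 32, 64), compression 4, strided shortcut convs; final BN;
        # dense head 64 -> 4 (+bias).  Convs are bias-free; each BN has
        # gamma+beta per channel.
        net = build_resnet_1d(ModelConfig(task="classification", n_bands=400))
        stem = 1 * 16 * 7 + 2 * 16
        s0 = 2 * 16 + 16 * 4 + 2 * 4 + 4 * 4 * 3 + 2 * 4 + 4 * 16 + 16 * 16
        s1 = 2 * 16 + 16 * 8 + 2 * 8 + 8 * 8 * 3 + 2 * 8 + 8 * 32 + 16 * 32
        s2 = 2 * 32 + 32 * 16 + 2 * 16 + 16 * 16 * 3 + 2 * 16 + 16 * 64 + 32 * 64
        final = 2 * 64
        head = 64 * 4 + 4
        assert net.n_params() == stem + s0 + s1 + s2 + final + head

    def test_parameter_count_matches_hand_tally_3d(self):
        net = build_resnet_3d(
            ModelConfig(input_kind="cube", task="classification", n_bands=32, spatial_dims=(16, 16))
        )
        stem = 1 * 16 * 7**3 + 2 * 16
        s0 = 2 * 16 + 16 * 4 + 2 * 4 + 4 * 4 * 27 + 2 * 4 + 4 * 16 + 16 * 16
        s1 = 2 * 16 + 16 * 8 + 2 * 8 + 8 * 8 * 27 + 2 * 8 + 8 * 32 + 16 * 32
        s2 = 2 * 32 + 32 * 16 + 2 * 16 + 16 * 16 * 27 + 2 * 16 + 16 * 64 + 32 * 64
        final = 2 * 64
        head = 64 * 4 + 4
        assert net.n_params() == stem + s0 + s1 + s2 + final + head

    def test_trunks_identical_across_tasks(self):
        cls_net = build_resnet_1d(_cls_config())
        reg_net = build_resnet_1d(_cls_config(task="regression"))
        assert cls_net.trunk_param_shapes() == reg_net.trunk_param_shapes()
        head_cls = [p.value.shape for p in cls_net.head.params()]
        head_reg = [p.value.shape for p in reg_net.head.params()]
        assert head_cls != head_reg

    def test_too_few_bands_rejected(self):
        with pytest.raises(ValueError):
            build_resnet_1d(_cls_config(n_bands=16))
        with pytest.raises(ValueError):
            build_resnet_3d(
                ModelConfig(input_kind="cube", task="classification", n_bands=32, spatial_dims=(8, 8))
            )

    def test_task_defaults(self):
        cls = ModelConfig(task="classification", n_bands=40)
        reg = ModelConfig(task="regression", n_bands=40)
        assert (cls.resolved_epochs, cls.resolved_lr) == (1000, 0.01)
        assert (reg.resolved_epochs, reg.resolved_lr) == (1500, 0.0001)
        assert cls.dropout == reg.dropout == 0.3


class TestTraining:
    def test_overfits_separable_spectra(self, rng):
        X = np.concatenate([rng.normal(-1, 0.1, (4, 40)), rng.normal(1, 0.1, (4, 40))])
        y = np.array([0] * 4 + [3] * 4)
        config = _cls_config(epochs=200, batch_size=8)
        tm = train(build_resnet_1d(config), X, y, config=config)
        assert np.mean(tm.predict(X) == y) == 1.0

    def test_loss_decreases(self, rng):
        X = rng.normal(size=(24, 40))
        y = (X[:, :10].mean(axis=1) > 0).astype(int)
        config = _cls_config(epochs=60)
        tm = train(build_resnet_1d(config), X, y, config=config)
        assert tm.log["train_loss"].iloc[-1] < tm.log["train_loss"].iloc[0]

    def test_regression_capacity_on_linear_target(self, rng):
        X = rng.normal(size=(48, 40))
        w = rng.normal(size=40) / 40
        y = X @ w
        config = ModelConfig(task="regression", n_bands=40, epochs=1000, learning_rate=0.005, seed=1)
        tm = train(build_resnet_1d(config), X, y, config=config)
        rmse = np.sqrt(np.mean((tm.predict(X) - y) ** 2))
        assert rmse < 0.1 * y.std()

    def test_nan_loss_raises_with_epoch(self, rng):
        X = rng.normal(size=(8, 40))
        X[0, 0] = np.nan
        config = _cls_config(epochs=5)
        with pytest.raises(TrainingError):
            train(build_resnet_1d(config), X, np.zeros(8, dtype=int), config=config)

    def test_empty_training_set_rejected(self):
        config = _cls_config()
        with pytest.raises(ValueError):
            train(build_resnet_1d(config), np.empty((0, 40)), np.empty(0), config=config)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(16, 40))
        y = rng.integers(0, 4, 16)
        config = _cls_config(epochs=20)
        a = train(build_resnet_1d(config), X, y, config=config)
        b = train(build_resnet_1d(config), X, y, config=config)
        np.testing.assert_array_equal(a.log["train_loss"], b.log["train_loss"])
        np.testing.assert_array_equal(a.forward_raw(X), b.forward_raw(X))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(20, 40))
    y = rng.integers(0, 4, 20)
    config = _cls_config(epochs=30)
    return train(build_resnet_1d(config), X, y, X, y, config=config), X, y


class TestPrediction:

    def test_probabilities_sum_to_one(self, fitted, rng):
        tm, X, _ = fitted
        probs = predict(tm, X)["probabilities"]
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_is_deterministic(self, fitted):
        tm, X, _ = fitted
        np.testing.assert_array_equal(tm.forward_raw(X), tm.forward_raw(X))

    def test_duplicate_inputs_identical_outputs(self, fitted):
        tm, X, _ = fitted
        doubled = np.concatenate([X[:1], X[:1]])
        out = tm.forward_raw(doubled)
        np.testing.assert_array_equal(out[0], out[1])

    def test_dropout_active_only_in_training(self, fitted):
        tm, X, _ = fitted
        a = tm.net.forward(tm._standardized(X), train=True)
        b = tm.net.forward(tm._standardized(X), train=True)
        assert not np.array_equal(a, b)  # dropout masks differ between passes

    def test_shape_mismatch_rejected(self, fitted):
        tm, _, _ = fitted
        with pytest.raises(ValueError):
            tm.predict(np.zeros((2, 39)))

    def test_checkpoint_roundtrip(self, fitted, tmp_path):
        tm, X, _ = fitted
        path = tmp_path / "model.npz"
        save_model(tm, path)
        loaded = load_model(path)
        np.testing.assert_allclose(loaded.forward_raw(X), tm.forward_raw(X), atol=1e-12)


class Test3DSmoke:
    def test_downscaled_cube_builds_and_runs_quickly(self, rng):
        import time

        config = ModelConfig(input_kind="cube", task="classification", n_bands=32, spatial_dims=(16, 16))
        net = build_resnet_3d(config)
        x = rng.normal(size=(2, 1, 16, 16, 32)).astype(np.float32)
        t0 = time.time()
        out = net.forward(x, train=False)
        assert time.time() - t0 < 1.0
        assert out.shape == (2, 4) and np.all(np.isfinite(out))

    def test_constant_input_finite_logits(self):
        config = ModelConfig(input_kind="cube", task="classification", n_bands=32, spatial_dims=(16, 16))
        net = build_resnet_3d(config)
        out = net.forward(np.full((1, 1, 16, 16, 32), 0.5, dtype=np.float32), train=False)
        assert np.all(np.isfinite(out))

    def test_full_scale_contract_builds(self):
        config = ModelConfig(input_kind="cube", task="classification", n_bands=400, spatial_dims=(85, 85))
        net = build_resnet_3d(config)
        assert net.config.spatial_dims == (85, 85)
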