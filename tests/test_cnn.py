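"""CNN layers against scalar-loop oracles, training behavior, serialization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscnn.cnn import (
    CNNConfig,
    activate,
    conv_output_len,
    convolve,
    dense_forward,
    forward,
    gradients,
    init_model,
    load_model,
    loss,
    max_pool,
    predict,
    save_model,
    softmax,
    train,
    train_loocv,
)

import oracles


class TestConvolve:
    def test_zero_input_gives_zero_maps(self):
        out = convolve(np.zeros(20), np.ones((3, 5)))
        assert out.shape == (3, 16)
        np.testing.assert_array_equal(out, 0.0)

    def test_known_small_example(self):
        out = convolve(np.array([1.0, 2.0, 3.0, 4.0]), np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(out, [[3.0, 5.0, 7.0]])

    def test_output_length_200_minus_10_plus_1(self):
        out = convolve(np.arange(200.0), np.ones((1, 10)))
        assert out.shape[1] == 191
        assert conv_output_len(200, 10, 1) == 191

    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            convolve(np.zeros(3), np.ones((1, 5)))

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = rng.integers(5, 21)
            m = rng.integers(1, min(n, 6) + 1)
            k = rng.integers(1, 4)
            stride = rng.integers(1, 3)
            x = rng.normal(size=n)
            w = rng.normal(size=(k, m))
            np.testing.assert_allclose(
                convolve(x, w, stride), oracles.conv_loops(x, w, stride),
                atol=1e-10)


class TestActivate:
    def test_rectifier_examples(self):
        assert activate(np.array(0.0), "relu") == 0.0
        np.testing.assert_array_equal(
            activate(np.array([-1.0, 2.0]), "relu"), [0.0, 2.0])

    def test_matches_scalar_oracle(self, rng):
        u = rng.normal(size=(3, 7)) * 5
        for kind in ("relu", "sigmoid"):
            np.testing.assert_allclose(
                activate(u, kind), oracles.activate_loops(u, kind), atol=1e-10)


class TestMaxPool:
    def test_200_halves_to_100(self):
        assert max_pool(np.arange(200.0), 2, 2).shape == (100,)

    def test_known_example(self):
        np.testing.assert_array_equal(
            max_pool(np.array([1.0, 3.0, 2.0, 5.0]), 2, 2), [3.0, 5.0])

    def test_constant_input_gives_constant_reduced_output(self):
        out = max_pool(np.full((2, 10), 1.5), 2, 2)
        assert out.shape == (2, 5)
        np.testing.assert_array_equal(out, 1.5)

    def test_input_shorter_than_pool_rejected(self):
        with pytest.raises(ValueError):
            max_pool(np.zeros(1), 2, 2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            length = rng.integers(2, 20)
            pl = rng.integers(1, min(4, length) + 1)
            stride = rng.integers(1, 4)
            y = rng.normal(size=(2, length))
            np.testing.assert_allclose(
                max_pool(y, pl, stride),
                oracles.max_pool_loops(y, pl, stride), atol=1e-12)


class TestDense:
    def test_zero_weights_output_bias(self):
        out = dense_forward(np.ones(4), np.zeros((2, 4)), np.array([1.5, -2.0]))
        np.testing.assert_array_equal(out, [1.5, -2.0])

    def test_single_unit_example(self):
        out = dense_forward(np.array([2.0]), np.array([[3.0]]), np.array([1.0]))
        np.testing.assert_array_equal(out, [7.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dense_forward(np.ones(3), np.ones((2, 4)), np.zeros(2))

    def test_matches_double_loop_oracle(self, rng):
        flat = rng.normal(size=12)
        w = rng.normal(size=(2, 12))
        b = rng.normal(size=2)
        np.testing.assert_allclose(
            dense_forward(flat, w, b), oracles.dense_loops(flat, w, b),
            atol=1e-10)


class TestSoftmax:
    def test_symmetric_input(self):
        np.testing.assert_allclose(softmax(np.zeros(2)), [0.5, 0.5])

    def test_known_value(self):
        p = softmax(np.array([1.0, 0.0]))
        np.testing.assert_allclose(p, [np.e / (1 + np.e), 1 / (1 + np.e)])
        assert p[0] == pytest.approx(0.7311, abs=1e-4)

    def test_large_input_no_overflow(self):
        p = softmax(np.array([1000.0, 0.0]))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=6),
           st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_shift_invariance_and_normalization(self, u, shift):
        u = np.array(u)
        p = softmax(u)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p > 0).all()
        np.testing.assert_allclose(softmax(u + shift), p, atol=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        assert loss(np.array([1.0, 0.0]), 0) == 0.0

    def test_uniform_prediction_log2(self):
        assert loss(np.array([0.5, 0.5]), 1) == pytest.approx(np.log(2))

    def test_monotone_in_true_class_probability(self):
        losses = [loss(np.array([p, 1 - p]), 0) for p in (0.2, 0.5, 0.9)]
        assert losses[0] > losses[1] > losses[2]

    def test_mse_variant(self):
        assert loss(np.array([1.0, 0.0]), 0, "mse") == 0.0
        assert loss(np.array([0.5, 0.5]), 0, "mse") == pytest.approx(0.5)


class TestForward:
    def test_probabilities_sum_to_one(self, tiny_cnn_config, rng):
        model = init_model(tiny_cnn_config, 12, seed=1)
        p, _ = forward(model, rng.normal(size=12))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_dense_layer_gives_uniform_probabilities(self, tiny_cnn_config, rng):
        model = init_model(tiny_cnn_config, 12, seed=1)
        model.dense_w[:] = 0.0
        model.dense_b[:] = 0.0
        p, _ = forward(model, rng.normal(size=12))
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_length_mismatch_rejected(self, tiny_cnn_config):
        model = init_model(tiny_cnn_config, 12, seed=1)
        with pytest.raises(ValueError):
            forward(model, np.zeros(13))

    @pytest.mark.parametrize("activation", ["sigmoid", "relu"])
    def test_composed_forward_matches_scalar_oracle(self, activation, rng):
        cfg = CNNConfig(kernel_len=3, n_kernels=2, pool_len=2, pool_stride=2,
                        activation=activation, epochs=1)
        model = init_model(cfg, 12, seed=7)
        for _ in range(20):
            x = rng.normal(size=12)
            p, _ = forward(model, x)
            expected = oracles.forward_loops(
                x, model.kernels, model.dense_w, model.dense_b,
                activation=activation)
            np.testing.assert_allclose(p, expected, atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("activation", ["sigmoid", "relu"])
    @pytest.mark.parametrize("loss_kind", ["cross_entropy", "mse"])
    def test_backprop_matches_central_finite_differences(
            self, activation, loss_kind, rng):
        cfg = CNNConfig(kernel_len=3, n_kernels=2, pool_len=2, pool_stride=2,
                        activation=activation, loss=loss_kind, epochs=1)
        model = init_model(cfg, 12, seed=4)
        X = rng.random((5, 12))
        y = np.array([0, 1, 0, 1, 1])
        _, analytic = gradients(model, X, y)
        numeric = oracles.numerical_gradients(model, X, y)
        for name in analytic:
            scale = max(np.abs(numeric[name]).max(), 1e-12)
            rel = np.abs(analytic[name] - numeric[name]).max() / scale
            assert rel < 1e-5, f"{name}: rel err {rel:.2e}"


class TestTrain:
    def _toy_separable(self, rng, n_per_class=4, n=20):
        data = []
        for label in (0, 1):
            for _ in range(n_per_class):
                data.append((label + rng.normal(0, 0.05, n), label))
        return data

    def test_zero_learning_rate_leaves_weights_at_initialization(self, rng):
        data = self._toy_separable(rng)
        cfg = CNNConfig(learning_rate=0.0, epochs=10, kernel_len=3,
                        n_kernels=2)
        model, _ = train(data, cfg, seed=5)
        init = init_model(cfg, 20, seed=5)
        np.testing.assert_array_equal(model.kernels, init.kernels)
        np.testing.assert_array_equal(model.dense_w, init.dense_w)

    def test_separable_toy_reaches_full_training_accuracy(self, rng):
        data = self._toy_separable(rng)
        cfg = CNNConfig(epochs=500, kernel_len=3, n_kernels=2)
        model, trace = train(data, cfg, seed=2)
        correct = [predict(model, x)[0] == lab for x, lab in data]
        assert all(correct)
        assert trace[-1] < trace[0]

    def test_training_is_deterministic_given_seed(self, rng):
        data = self._toy_separable(rng)
        cfg = CNNConfig(epochs=50, kernel_len=3, n_kernels=2)
        m1, t1 = train(data, cfg, seed=9)
        m2, t2 = train(data, cfg, seed=9)
        np.testing.assert_array_equal(m1.kernels, m2.kernels)
        np.testing.assert_array_equal(t1, t2)

    def test_single_class_dataset_rejected(self, rng):
        data = [(rng.normal(size=20), 0) for _ in range(4)]
        with pytest.raises(ValueError):
            train(data, CNNConfig(epochs=1, kernel_len=3))

    def test_per_sample_mode_runs_and_is_deterministic(self, rng):
        data = self._toy_separable(rng)
        cfg = CNNConfig(epochs=20, kernel_len=3, n_kernels=2,
                        batch_mode="per_sample", max_restarts=0)
        m1, _ = train(data, cfg, seed=3)
        m2, _ = train(data, cfg, seed=3)
        np.testing.assert_array_equal(m1.kernels, m2.kernels)


class TestTrainLoocvBatched:
    def test_matches_per_fold_training(self, rng):
        """The fold-batched trainer and the plain per-fold trainer are the
        same algorithm; models agree to single precision."""
        X = np.vstack([rng.random(20) + lab for lab in [0] * 4 + [1] * 4])
        y = np.array([0] * 4 + [1] * 4)
        cfg = CNNConfig(epochs=40, kernel_len=3, n_kernels=2, max_restarts=0)
        seeds = list(range(50, 58))
        models = train_loocv(X, y, cfg, fold_seeds=seeds)
        for f in (0, 5):
            solo, _ = train(
                [(X[i], y[i]) for i in range(8) if i != f], cfg, seed=seeds[f])
            np.testing.assert_allclose(models[f].kernels, solo.kernels,
                                       rtol=1e-4, atol=1e-4)
            np.testing.assert_allclose(models[f].dense_w, solo.dense_w,
                                       rtol=1e-4, atol=1e-4)

    def test_fold_with_single_class_training_set_rejected(self):
        X = np.random.default_rng(0).random((3, 12))
        y = np.array([0, 1, 1])
        with pytest.raises(ValueError):
            train_loocv(X, y, CNNConfig(epochs=1, kernel_len=3))


class TestPredict:
    def test_tie_resolves_to_class_zero(self, tiny_cnn_config):
        model = init_model(tiny_cnn_config, 12, seed=1)
        model.dense_w[:] = 0.0
        model.dense_b[:] = 0.0
        label, p = predict(model, np.zeros(12))
        assert label == 0
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_higher_probability_wins(self, tiny_cnn_config):
        model = init_model(tiny_cnn_config, 12, seed=1)
        model.dense_w[:] = 0.0
        model.dense_b[:] = np.array([-1.0, 1.0])
        assert predict(model, np.zeros(12))[0] == 1


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path, rng):
        cfg = CNNConfig(kernel_len=4, n_kernels=3, epochs=7)
        model = init_model(cfg, 16, seed=11)
        model.kernels += rng.normal(size=model.kernels.shape)
        path = save_model(model, tmp_path / "model.json")
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.kernels, model.kernels)
        np.testing.assert_array_equal(loaded.dense_w, model.dense_w)
        np.testing.assert_array_equal(loaded.dense_b, model.dense_b)
        assert loaded.config == model.config
        assert loaded.n_features == model.n_features

    def test_wrong_format_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            load_model(p)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"learning_rate": -0.1},
        {"momentum": 1.0},
        {"kernel_len": 0},
        {"activation": "swish"},
        {"loss": "hinge"},
        {"batch_mode": "minibatch"},
        {"max_restarts": -1},
    ])
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CNNConfig(**kwargs)

    def test_fast_profile_only_reduces_epochs(self):
        cfg = CNNConfig()
        fast = cfg.fast()
        assert fast.epochs == 200
        assert dataclasses.replace(fast, epochs=cfg.epochs) == cfg
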