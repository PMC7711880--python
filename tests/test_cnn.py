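import math

import numpy as np
import pytest

from sbocad import cnn, sbo
from sbocad.pipeline import dice


def tiny_net(seed=0):
    """8x8 input, one 3x3 conv (2 filters), pool, small FC head, 2 classes."""
    return cnn.patch_architecture(patch_size=8, channels=1, filters=(2,),
                                  kernels=(3,), dense=4, seed=seed)


def finite_difference_grad(net, x, d, theta, eps=1e-5):
    p0 = net.get_params()
    fd = np.zeros_like(p0)
    for i in range(p0.size):
        for sign, store in ((1, "plus"), (-1, "minus")):
            v = p0.copy()
            v[i] += sign * eps
            net.set_params(v)
            z = cnn.softmax(net.forward(x))
            val = cnn.cross_entropy_loss(z, d, net.weight_tensors(), theta)
            if sign == 1:
                lp = val
            else:
                lm = val
        fd[i] = (lp - lm) / (2 * eps)
    net.set_params(p0)
    return fd


def toy_batch(rng, n=6):
    x = rng.random((n, 8, 8, 1))
    d = np.zeros((n, 2))
    d[np.arange(n), rng.integers(0, 2, n)] = 1.0
    return x, d


class TestConvForward:
    def test_one_by_one_identity(self, rng):
        x = rng.random((2, 5, 5, 1))
        k = np.ones((1, 1, 1, 1))
        out = cnn.conv_forward(x, k, np.zeros(1))
        assert np.allclose(out, x)

    def test_ones_kernel_sums_window(self):
        x = np.ones((1, 5, 5, 1))
        k = np.ones((3, 3, 1, 1))
        out = cnn.conv_forward(x, k, np.zeros(1))
        assert out.shape == (1, 3, 3, 1)
        assert np.allclose(out, 9.0)

    def test_matches_sliding_window_oracle(self, rng):
        x = rng.standard_normal((2, 7, 6, 3))
        k = rng.standard_normal((3, 3, 3, 4))
        b = rng.standard_normal(4)
        out = cnn.conv_forward(x, k, b)
        for n in range(2):
            for i in range(5):
                for j in range(4):
                    for f in range(4):
                        ref = (x[n, i:i + 3, j:j + 3, :] * k[..., f]).sum() + b[f]
                        assert out[n, i, j, f] == pytest.approx(ref)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            cnn.conv_forward(np.zeros((1, 2, 2, 1)), np.zeros((3, 3, 1, 1)),
                             np.zeros(1))


class TestActivations:
    def test_relu_values_and_idempotence(self, rng):
        assert cnn.relu(np.array(-3.0)) == 0
        assert cnn.relu(np.array(2.5)) == 2.5
        x = rng.standard_normal((4, 4))
        assert np.array_equal(cnn.relu(cnn.relu(x)), cnn.relu(x))

    def test_softmax_symmetry_and_closed_form(self):
        assert np.allclose(cnn.softmax(np.zeros((1, 2))), 0.5)
        out = cnn.softmax(np.array([[0.0, math.log(3.0)]]))
        assert np.allclose(out, [[0.25, 0.75]])

    def test_softmax_shift_invariance(self, rng):
        f = rng.standard_normal((3, 5))
        assert np.allclose(cnn.softmax(f), cnn.softmax(f + 100.0))

    def test_softmax_is_distribution(self, rng):
        z = cnn.softmax(rng.standard_normal((10, 4)) * 50)
        assert np.allclose(z.sum(axis=1), 1.0)
        assert np.all(z >= 0)


class TestMaxPool:
    def test_two_by_two_block(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 2, 2, 1)
        assert cnn.max_pool(x)[0, 0, 0, 0] == 4.0

    def test_constant_halves_resolution(self):
        x = np.full((1, 8, 8, 3), 0.3)
        out = cnn.max_pool(x)
        assert out.shape == (1, 4, 4, 3)
        assert np.allclose(out, 0.3)

    def test_output_dominates_inputs(self, rng):
        x = rng.standard_normal((2, 6, 6, 2))
        out = cnn.max_pool(x)
        for n in range(2):
            for i in range(3):
                for j in range(3):
                    block = x[n, 2 * i:2 * i + 2, 2 * j:2 * j + 2, :]
                    assert np.all(out[n, i, j, :] == block.max(axis=(0, 1)))

    def test_odd_dims_replicate_padded(self, rng):
        out = cnn.max_pool(rng.random((1, 5, 5, 1)))
        assert out.shape == (1, 3, 3, 1)


class TestLosses:
    def test_perfect_prediction_zero_loss(self):
        z = np.array([[0.0, 1.0]])
        d = np.array([[0.0, 1.0]])
        assert cnn.cross_entropy_loss(z, d) == pytest.approx(0.0, abs=1e-11)

    def test_half_probability_gives_ln2(self):
        z = np.array([[0.5, 0.5]])
        d = np.array([[1.0, 0.0]])
        assert cnn.cross_entropy_loss(z, d) == pytest.approx(math.log(2.0))

    def test_zero_weights_zero_penalty(self):
        z = np.array([[0.5, 0.5]])
        d = np.array([[1.0, 0.0]])
        with_pen = cnn.cross_entropy_loss(z, d, [np.zeros((3, 3))], theta=2.0)
        assert with_pen == pytest.approx(math.log(2.0))

    def test_penalty_value(self):
        z = np.array([[1.0, 0.0]])
        d = np.array([[1.0, 0.0]])
        w = [np.full((2, 2), 3.0)]
        assert cnn.cross_entropy_loss(z, d, w, theta=0.5) == pytest.approx(
            0.5 * 0.5 * 4 * 9, abs=1e-9)

    def test_mse_error_zero_for_perfect_outputs(self):
        d = np.eye(3)
        assert cnn.output_mse(d, d) == 0.0

    def test_mse_error_hand_value(self):
        o = np.array([[0.8, 0.2], [0.4, 0.6]])
        d = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = (0.04 + 0.04 + 0.16 + 0.16) / 2
        assert cnn.output_mse(o, d) == pytest.approx(expected)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        net = tiny_net(seed=0)
        x, d = toy_batch(rng)
        theta = 0.01
        _, g = net.loss_and_gradients(x, d, theta=theta)
        fd = finite_difference_grad(net, x, d, theta)
        rel = np.abs(g - fd) / np.maximum(1e-8, np.abs(g) + np.abs(fd))
        assert rel.max() < 1e-4

    def test_zero_input_zeroes_first_conv_weight_grads(self):
        net = tiny_net(seed=1)
        conv = net.layers[0]
        conv.b = np.full_like(conv.b, 0.1)  # keep ReLU open at zero input
        x = np.zeros((4, 8, 8, 1))
        d = np.tile([1.0, 0.0], (4, 1))
        net.loss_and_gradients(x, d)
        assert np.allclose(conv.dW, 0.0)
        # bias gradients still propagate
        assert not np.allclose(conv.db, 0.0)

    def test_theta_contribution_is_theta_times_weights(self, rng):
        net = tiny_net(seed=2)
        x, d = toy_batch(rng)
        _, g0 = net.loss_and_gradients(x, d, theta=0.0)
        _, g1 = net.loss_and_gradients(x, d, theta=0.3)
        expected = np.zeros_like(g0)
        i = 0
        for layer in net.layers:
            if not layer.has_weights:
                continue
            expected[i:i + layer.W.size] = 0.3 * layer.W.ravel()
            i += layer.W.size + layer.b.size
        assert np.allclose(g1 - g0, expected, atol=1e-10)

    def test_flatten_unflatten_roundtrip(self, rng):
        net = tiny_net(seed=3)
        vec = net.get_params()
        perturbed = vec + rng.standard_normal(vec.size)
        net.set_params(perturbed)
        assert np.array_equal(net.get_params(), perturbed)
        assert vec.size == net.n_params


def bright_dark_batch(seed=1, n=40):
    rng = np.random.default_rng(seed)
    xb = 0.8 + 0.05 * rng.standard_normal((n, 8, 8, 1))
    xd = 0.2 + 0.05 * rng.standard_normal((n, 8, 8, 1))
    x = np.vstack([xb, xd])
    d = np.zeros((2 * n, 2))
    d[:n, 0] = 1.0
    d[n:, 1] = 1.0
    return x, d


class TestTraining:
    def test_zero_learning_rate_keeps_params(self, rng):
        net = tiny_net(seed=4)
        x, d = toy_batch(rng)
        before = net.get_params()
        cnn.gd_train(net, x, d, cnn.TrainConfig(learning_rate=0.0,
                                                iterations=5,
                                                dropout_active=False))
        assert np.array_equal(net.get_params(), before)

    def test_one_step_equals_params_minus_lr_grad(self, rng):
        net = tiny_net(seed=5)
        x, d = toy_batch(rng)
        p0 = net.get_params()
        fd = finite_difference_grad(net, x, d, theta=0.0) / x.shape[0]
        cnn.gd_train(net, x, d, cnn.TrainConfig(learning_rate=0.05,
                                                iterations=1, theta=0.0,
                                                dropout_active=False))
        assert np.allclose(net.get_params(), p0 - 0.05 * fd, atol=1e-6)

    def test_loss_strictly_decreases_on_separable_toy(self):
        x, d = bright_dark_batch()
        net = tiny_net(seed=1)
        h = cnn.gd_train(net, x, d, cnn.TrainConfig(learning_rate=0.1,
                                                    iterations=50, theta=0.0,
                                                    dropout_active=False))
        assert all(a > b for a, b in zip(h, h[1:]))

    def test_sbo_refine_zero_budget_is_noop(self, rng):
        net = tiny_net(seed=6)
        x, d = toy_batch(rng)
        before = net.get_params()
        cfg = sbo.SBOConfig(population_size=5, max_iterations=0,
                            lower_bounds=before - 0.5,
                            upper_bounds=before + 0.5, seed=0)
        cnn.sbo_refine(net, x, d, cfg)
        assert np.array_equal(net.get_params(), before)

    def test_sbo_refine_never_increases_error(self, rng):
        net = tiny_net(seed=7)
        x, d = bright_dark_batch(seed=2, n=10)
        before = cnn.output_mse(net.predict_proba(x), d)
        theta0 = net.get_params()
        cfg = sbo.SBOConfig(population_size=8, max_iterations=4,
                            lower_bounds=theta0 - 0.3,
                            upper_bounds=theta0 + 0.3, seed=1)
        cnn.sbo_refine(net, x, d, cfg)
        after = cnn.output_mse(net.predict_proba(x), d)
        assert after <= before + 1e-12


class TestDropout:
    def test_drop_fraction_near_ratio(self):
        rng = np.random.default_rng(0)
        layer = cnn.Dropout(0.6)
        out = layer.forward(np.ones((100, 1000)), train=True, rng=rng)
        frac = (out == 0).mean()
        assert frac == pytest.approx(0.6, rel=0.02)

    def test_inference_is_identity(self, rng):
        layer = cnn.Dropout(0.6)
        x = rng.random((5, 7))
        assert layer.forward(x, train=False) is x

    def test_inverted_scaling_preserves_mean(self):
        rng = np.random.default_rng(1)
        layer = cnn.Dropout(0.6)
        out = layer.forward(np.ones((200, 500)), train=True, rng=rng)
        assert out.mean() == pytest.approx(1.0, rel=0.02)


class TestArchitectures:
    def test_table_geometry_forward_shape(self):
        net = cnn.table_architecture(classes=2, filters=(2, 2, 2), dense=16)
        out = net.forward(np.zeros((1, 256, 256, 3)))
        assert out.shape == (1, 2)

    def test_hyperparameter_search_returns_valid_windows(self, rng):
        x, d = bright_dark_batch(seed=3, n=8)
        (k1, k2), res = cnn.sbo_hyperparameter_search(
            x, d, patch_size=8, window_max=4,
            sbo_config=sbo.SBOConfig(population_size=4, max_iterations=2,
                                     seed=0,
                                     lower_bounds=np.array([2.0, 2.0]),
                                     upper_bounds=np.array([4.0, 4.0])),
            gd_iters=10)
        assert 2 <= k1 <= 4 and 2 <= k2 <= 4
        assert np.isfinite(res.best_objective)


class TestSegment:
    def test_mask_contract(self, small_grays, trained_segmenter):
        mask = cnn.segment(small_grays[12], trained_segmenter, 16, 8)
        assert mask.shape == small_grays[12].shape
        assert mask.dtype == bool

    def test_dice_on_held_out_synthetic_image(self, small_dataset,
                                              small_grays, trained_segmenter):
        scores = [dice(cnn.segment(small_grays[i], trained_segmenter, 16, 4),
                       small_dataset.masks[i]) for i in (12, 13, 14, 15)]
        assert float(np.mean(scores)) >= 0.85

    def test_background_only_image_gives_empty_mask(self, trained_segmenter):
        img = np.full((64, 64), 0.75)
        mask = cnn.segment(img, trained_segmenter, 16, 8)
        assert not mask.any()

    def test_too_small_image_rejected(self, trained_segmenter):
        with pytest.raises(ValueError):
            cnn.segment(np.zeros((8, 8)), trained_segmenter, 16, 4)
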