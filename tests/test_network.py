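"""Network components: convolution/pooling arithmetic, softmax heads, the
gradient-reversal layer, the lambda ramp, and finite-difference validation of
the hand-written backward passes."""

import numpy as np
import pytest

from dannseq import network as nn
from dannseq.network import (
    DannConfig,
    domain_classifier,
    feature_extractor,
    grad_reverse,
    grad_reverse_backward,
    label_predictor,
    lambda_schedule,
    load_checkpoint,
    save_checkpoint,
    score,
)


class TestConfig:
    def test_feature_width_full_model(self):
        # valid padding: 101 -> 97 -> 47 -> 43 -> 20; 20 positions x 48 kernels
        assert DannConfig().feature_width == 960

    def test_feature_width_reduced_model(self):
        assert DannConfig(n_kernels_1=8, n_kernels_2=12).feature_width == 240

    @pytest.mark.parametrize(
        "bad", [dict(dropout_rate=1.0), dict(alpha=-0.1), dict(n_kernels_1=0), dict(patience=0)]
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            DannConfig(**bad)


class TestLambdaSchedule:
    def test_zero_progress_gives_zero(self):
        assert lambda_schedule(0.0) == 0.0

    def test_full_progress_matches_arbitrary_precision(self):
        import sympy

        expected = float(2 / (1 + sympy.exp(-10)) - 1)  # evaluated symbolically
        assert abs(lambda_schedule(1.0) - expected) < 1e-10
        assert abs(lambda_schedule(1.0) - 0.99991) < 1e-5

    def test_strictly_increasing_on_grid(self):
        grid = np.linspace(0, 1, 100)
        vals = [lambda_schedule(float(p)) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[30] < vals[60]

    @pytest.mark.parametrize("p", [-0.01, 1.01])
    def test_out_of_range_progress_rejected(self, p):
        with pytest.raises(ValueError):
            lambda_schedule(p)


class TestFeatureExtractor:
    def test_zero_input_zero_biases_gives_zero_features(self, small_config):
        params = nn.init_params(small_config)
        x = np.zeros((3, 4, 101))
        z = feature_extractor(x, params, small_config)
        assert z.shape == (3, small_config.feature_width)
        assert np.all(z == 0)  # ReLU(0)=0 and max of zeros = 0

    def test_single_kernel_matches_sliding_window_oracle(self, rng):
        cfg = DannConfig(n_kernels_1=1, n_kernels_2=1, dtype="float64")
        x = rng.random((1, 4, 101))
        W = rng.random((1, 4, 5))
        y, _ = nn.conv1d_forward(x, W, np.zeros(1))
        # hand-rolled sliding-window correlation
        expected = np.array(
            [np.sum(x[0, :, i : i + 5] * W[0]) for i in range(97)]
        )
        np.testing.assert_allclose(y[0, 0], expected, atol=1e-12)

    def test_planted_kmer_activation_dominates_at_planted_position(self, rng):
        from dannseq.sequences import one_hot_encode

        seq = "".join(rng.choice(list("ACGT"), size=101))
        kmer = "TGACG"
        pos = 40
        seq = seq[:pos] + kmer + seq[pos + 5 :]
        x = one_hot_encode(seq)[None]
        W = one_hot_encode((kmer + "A" * 96))[None, :, :5] * 1.0  # kernel = the 5-mer itself
        y, _ = nn.conv1d_forward(x, W, np.zeros(1))
        assert y[0, 0].argmax() == pos
        assert y[0, 0, pos] == 5.0  # perfect match: 5 positions agree

    def test_shape_mismatch_is_loud(self, small_config):
        params = nn.init_params(small_config)
        with pytest.raises(ValueError, match="expected"):
            feature_extractor(np.zeros((2, 4, 50)), params, small_config)


class TestHeads:
    def test_zero_weights_give_half_half(self, small_config):
        params = {k: np.zeros_like(v) for k, v in nn.init_params(small_config).items()}
        z = np.random.default_rng(0).random((7, small_config.feature_width))
        probs = label_predictor(z, params, small_config)
        np.testing.assert_allclose(probs, 0.5)
        probs_d = domain_classifier(z, params, small_config, lam=1.0)
        np.testing.assert_allclose(probs_d, 0.5)

    def test_probabilities_sum_to_one(self, small_config, rng):
        params = nn.init_params(small_config)
        z = rng.standard_normal((1000, small_config.feature_width))
        for probs in (
            label_predictor(z, params, small_config),
            domain_classifier(z, params, small_config, lam=0.5),
        ):
            assert probs.min() > 0
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_monotone_in_own_logit(self):
        logits = np.array([[0.3, -0.2]])
        base = nn.softmax(logits)[0, 0]
        bumped = nn.softmax(logits + np.array([[0.7, 0.0]]))[0, 0]
        assert bumped > base

    def test_width_mismatch_is_loud(self, small_config, rng):
        params = nn.init_params(small_config)
        z = rng.random((2, small_config.feature_width + 1))
        with pytest.raises(ValueError, match="expected"):
            label_predictor(z, params, small_config)
        with pytest.raises(ValueError, match="expected"):
            domain_classifier(z, params, small_config, lam=1.0)


class TestGradReverse:
    def test_forward_is_bit_identical(self, rng):
        z = rng.standard_normal((5, 16))
        out = grad_reverse(z, lam=0.37)
        assert np.array_equal(out, z)

    def test_backward_sum_loss_lambda_one(self):
        # downstream loss = sum(z): gradient is all ones, flipped to all -1
        g = grad_reverse_backward(np.ones((2, 4)), lam=1.0)
        np.testing.assert_array_equal(g, -np.ones((2, 4)))

    @pytest.mark.parametrize("lam", [0.0, 0.37, 1.0])
    def test_backward_matches_finite_difference(self, lam, rng):
        # downstream quadratic loss f(y) = sum(A * y^2) + sum(B * y)
        A = rng.random((3, 8)) + 0.5
        B = rng.standard_normal((3, 8))
        z = rng.standard_normal((3, 8))

        def loss(y):
            return float(np.sum(A * y**2) + np.sum(B * y))

        analytic_downstream = 2 * A * grad_reverse(z, lam) + B
        grad_at_input = grad_reverse_backward(analytic_downstream, lam)
        # central finite differences of the downstream loss
        fd = np.zeros_like(z)
        eps = 1e-6
        for i in np.ndindex(z.shape):
            zp, zm = z.copy(), z.copy()
            zp[i] += eps
            zm[i] -= eps
            fd[i] = (loss(zp) - loss(zm)) / (2 * eps)
        expected = -lam * fd
        scale = max(np.abs(expected).max(), 1e-12)
        assert np.abs(grad_at_input - expected).max() / scale < 1e-4


class TestScore:
    def test_zero_model_scores_half(self, small_config, rng):
        params = {k: np.zeros_like(v) for k, v in nn.init_params(small_config).items()}
        x = rng.random((6, 4, 101))
        np.testing.assert_allclose(score(x, params, small_config), 0.5)

    def test_inference_deterministic(self, small_config, rng):
        params = nn.init_params(small_config)
        x = rng.random((10, 4, 101))
        s1 = score(x, params, small_config)
        s2 = score(x, params, small_config)
        assert np.array_equal(s1, s2)

    def test_batch_equals_per_item(self, small_config, rng):
        params = nn.init_params(small_config)
        x = rng.random((9, 4, 101))
        batch = score(x, params, small_config)
        singles = np.concatenate([score(x[i : i + 1], params, small_config) for i in range(9)])
        np.testing.assert_allclose(batch, singles, atol=1e-12)


class TestBackwardPasses:
    """Central finite-difference validation of every hand-written gradient."""

    def test_full_network_gradients(self, rng):
        from dannseq.training import compute_gradients

        cfg = DannConfig(n_kernels_1=2, n_kernels_2=3, fc_width=5, dtype="float64", seed=11)
        params = nn.init_params(cfg)
        x = rng.random((6, 4, 101))
        binding = np.array([0, 1, 0, -1, 1, -1])
        domains = np.array([0, 0, 0, 1, 1, 1])
        lam, alpha = 0.73, 0.9

        def objective(p):
            from dannseq.training import domain_loss, prediction_loss

            z, _ = nn.features_forward(p, cfg, x, want_cache=False)
            labeled = binding >= 0
            probs_l, _ = nn._head_forward(z[labeled], p["lp1_W"], p["lp1_b"], p["lp2_W"], p["lp2_b"])
            pred = prediction_loss(probs_l, binding[labeled])
            # the GRL realizes -lambda on the domain path into theta_f; for the
            # scalar check we evaluate the two head objectives separately
            probs_d, _ = nn._head_forward(z, p["dc1_W"], p["dc1_b"], p["dc2_W"], p["dc2_b"])
            dom = domain_loss(probs_d, domains)
            return pred, dom

        _, _, grads = compute_gradients(params, cfg, x, binding, domains, lam, alpha,
                                        use_adversary=True, dropout_rng=None)
        eps = 1e-6
        for key in params:
            flat = params[key].ravel()
            sample = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for j in sample:
                orig = flat[j]
                flat[j] = orig + eps
                pred_p, dom_p = objective(params)
                flat[j] = orig - eps
                pred_m, dom_m = objective(params)
                flat[j] = orig
                if key in nn.THETA_L:
                    expected = (pred_p - pred_m) / (2 * eps)
                elif key in nn.THETA_D:
                    expected = alpha * (dom_p - dom_m) / (2 * eps)
                else:  # theta_f: label gradient minus lambda*alpha* domain gradient
                    expected = (pred_p - pred_m) / (2 * eps) - lam * alpha * (dom_p - dom_m) / (2 * eps)
                got = grads[key].ravel()[j]
                assert abs(got - expected) < 1e-6 * max(1.0, abs(expected)), (key, j)

    def test_domain_gradient_sign_property(self, rng):
        """theta_f gradient of the domain term equals -lambda times the
        gradient obtained with the GRL removed."""
        from dannseq.training import compute_gradients

        cfg = DannConfig(n_kernels_1=2, n_kernels_2=3, fc_width=5, dtype="float64", seed=2)
        params = nn.init_params(cfg)
        x = rng.random((4, 4, 101))
        binding = np.full(4, -1)  # isolate the domain path
        domains = np.array([0, 1, 0, 1])
        lam = 0.6
        _, _, g_with = compute_gradients(params, cfg, x, binding, domains, lam, 1.0,
                                         use_adversary=True, dropout_rng=None)
        # GRL "removed": lambda = -1 flips the sign back to a plain descent
        # direction; emulate by computing at lambda=1 and negating
        _, _, g_plain = compute_gradients(params, cfg, x, binding, domains, 1.0, 1.0,
                                          use_adversary=True, dropout_rng=None)
        for key in nn.THETA_F:
            np.testing.assert_allclose(g_with[key], lam * g_plain[key], rtol=1e-5, atol=1e-12)


class TestCheckpoint:
    def test_round_trip(self, small_config, tmp_path):
        params = nn.init_params(small_config)
        log = [{"epoch": 0, "val_auc": 0.7}]
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, params, small_config, log)
        params2, config2, log2 = load_checkpoint(path)
        assert config2 == small_config
        assert log2 == log
        for k in params:
            np.testing.assert_array_equal(params[k], params2[k])

    def test_shape_mismatch_fails_loudly(self, small_config, tmp_path):
        params = nn.init_params(small_config)
        params["lp1_W"] = params["lp1_W"][:, :-1]
        path = tmp_path / "bad.ckpt"
        save_checkpoint(path, params, small_config, [])
        with pytest.raises(ValueError, match="lp1_W"):
            load_checkpoint(path)
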