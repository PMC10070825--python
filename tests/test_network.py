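"""Architecture arithmetic, forward contracts, and backward correctness."""

import numpy as np
import pytest

from cardioseg.losses import LossWeights, combined_loss, one_hot, softmax_backward
from cardioseg.nn.functional import softmax
from cardioseg.nn.unet import (NetworkConfig, build_network, forward,
                               load_checkpoint, predict_mask, save_checkpoint)


class TestConfig:
    def test_encoder_widths_double_from_base_64(self):
        cfg = NetworkConfig(depth=4, base_channels=64, input_size=64)
        assert cfg.encoder_channels == [64, 128, 256, 512]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(depth=4, input_size=60)

    def test_decoder_concat_doubles_stage_channels(self):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        # first conv of each decoder stage takes 2x the stage width
        for dec, width in zip(net.dec, [8, 4]):
            assert dec.ops[0].w.data.shape[1] == 2 * width


class TestForward:
    def test_output_matches_input_spatial_size_with_4_channels(self):
        net = build_network(NetworkConfig(depth=3, base_channels=4, input_size=32))
        probs = forward(net, np.zeros((2, 32, 32), dtype=np.float32))
        assert probs.shape == (2, 4, 32, 32)

    def test_pixel_probabilities_sum_to_one(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        probs = forward(net, rng.normal(size=(3, 16, 16)).astype(np.float32))
        assert np.all(np.abs(probs.sum(axis=1) - 1.0) < 1e-6)
        assert np.all(probs >= 0)

    def test_zeroed_head_gives_uniform_quarter_probabilities(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        net.head.w.data[...] = 0
        net.head.b.data[...] = 0
        probs = forward(net, rng.normal(size=(1, 16, 16)).astype(np.float32))
        assert np.allclose(probs, 0.25, atol=1e-7)

    def test_eval_forward_is_deterministic(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        x = rng.normal(size=(2, 16, 16)).astype(np.float32)
        assert np.array_equal(forward(net, x), forward(net, x))

    def test_wrong_spatial_size_rejected_without_resizing(self):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        with pytest.raises(ValueError, match="no implicit resizing"):
            forward(net, np.zeros((1, 32, 32), dtype=np.float32))


class TestPredictMask:
    def test_argmax_decode_and_codomain(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        mask = predict_mask(net, rng.normal(size=(16, 16)).astype(np.float32))
        assert mask.shape == (16, 16)
        assert set(np.unique(mask)) <= {0, 1, 2, 3}

    def test_accepts_grayscale_slice_container(self, rng):
        from cardioseg.types import GrayscaleSlice
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        sl = GrayscaleSlice(rng.normal(size=(16, 16)).astype(np.float32))
        assert predict_mask(net, sl).shape == (16, 16)

    def test_uniform_probabilities_tie_break_to_background(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        net.head.w.data[...] = 0
        net.head.b.data[...] = 0
        mask = predict_mask(net, rng.normal(size=(16, 16)).astype(np.float32))
        assert np.all(mask == 0)


class TestParameterArithmetic:
    def test_doubling_base_channels_increases_parameter_count(self):
        n1 = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        n2 = build_network(NetworkConfig(depth=2, base_channels=8, input_size=16))
        assert n2.n_parameters() > n1.n_parameters()

    def test_parameter_count_is_deterministic_function_of_config(self):
        a = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16, seed=0))
        b = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16, seed=9))
        assert a.n_parameters() == b.n_parameters()

    def test_bilinear_up_mode_builds_and_runs(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16,
                                          up_mode="bilinear"))
        probs = forward(net, rng.normal(size=(1, 16, 16)).astype(np.float32))
        assert probs.shape == (1, 4, 16, 16)


class TestBackward:
    @pytest.mark.parametrize("up_mode", ["transpose", "bilinear"])
    def test_head_gradient_matches_finite_differences(self, rng, up_mode):
        """FD check on the classification head, the one parameter tensor
        with a kink-free (no downstream ReLU/pool) path to the loss; the
        layers behind kinks are covered by the exact adjoint identities."""
        cfg = NetworkConfig(depth=2, base_channels=3, input_size=8, seed=0,
                            up_mode=up_mode)
        net = build_network(cfg)
        x = rng.normal(size=(3, 1, 8, 8)).astype(np.float32)
        target = one_hot(rng.integers(0, 4, size=(3, 8, 8)))
        w = LossWeights()

        def loss():
            probs = softmax(net.forward_logits(x, training=True), axis=1)
            return combined_loss(probs, target, w)

        net.zero_grad()
        probs = softmax(net.forward_logits(x, training=True), axis=1)
        _, gp = combined_loss(probs, target, w, return_grad=True)
        net.backward(softmax_backward(probs, gp).astype(np.float32))

        for p in (net.head.w, net.head.b):
            d = rng.normal(size=p.data.shape).astype(np.float32)
            d /= np.linalg.norm(d)
            h = 1e-3
            orig = p.data.copy()
            p.data[...] = orig + h * d
            lp = loss()
            p.data[...] = orig - h * d
            lm = loss()
            p.data[...] = orig
            num = (lp - lm) / (2 * h)
            ana = float((p.grad * d).sum())
            assert num == pytest.approx(ana, rel=1e-3, abs=1e-6)

    def test_adam_steps_overfit_a_fixed_batch(self, rng):
        """End-to-end gradient sanity: repeated steps on one fixed batch
        drive the compound loss far down (a systematically wrong backward
        pass would stall or diverge)."""
        from cardioseg.nn.optim import Adam
        net = build_network(NetworkConfig(depth=2, base_channels=8,
                                          input_size=16, seed=0))
        x = rng.normal(size=(4, 1, 16, 16)).astype(np.float32)
        labels = np.zeros((4, 16, 16), dtype=np.int64)
        labels[:, 4:12, 4:12] = 3
        labels[:, 6:10, 6:10] = 2
        target = one_hot(labels)
        opt = Adam(net.params(), lr=3e-3)
        losses = []
        for _ in range(80):
            opt.zero_grad()
            probs = softmax(net.forward_logits(x, training=True), axis=1)
            loss, gp = combined_loss(probs, target, LossWeights(), return_grad=True)
            net.backward(softmax_backward(probs, gp).astype(np.float32))
            opt.step()
            losses.append(loss)
        assert losses[-1] < 0.2 * losses[0]

    def test_gradients_are_finite_everywhere(self, rng):
        net = build_network(NetworkConfig(depth=2, base_channels=3, input_size=8))
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        target = one_hot(rng.integers(0, 4, size=(2, 8, 8)))
        net.zero_grad()
        probs = softmax(net.forward_logits(x, training=True), axis=1)
        _, gp = combined_loss(probs, target, LossWeights(), return_grad=True)
        net.backward(softmax_backward(probs, gp))
        for p in net.params():
            assert np.all(np.isfinite(p.grad)), p.name


class TestAdjoints:
    """Exact adjoint identities <J d, u> == <d, J^T u> for the linear maps."""

    def test_conv3x3_adjoint_identity(self, rng):
        from cardioseg.nn import functional as F
        x = rng.normal(size=(2, 3, 6, 6))
        W = rng.normal(size=(5, 3, 3, 3))
        b = rng.normal(size=5)
        dx_dir = rng.normal(size=x.shape)
        u = rng.normal(size=(2, 5, 6, 6))
        y0, cols = F.conv3x3_forward(x, W, b)
        y1, _ = F.conv3x3_forward(x + dx_dir, W, b)
        dxT, dW, _ = F.conv3x3_backward(u, cols, W)
        assert ((y1 - y0) * u).sum() == pytest.approx((dx_dir * dxT).sum(), rel=1e-10)
        dW_dir = rng.normal(size=W.shape)
        y2, _ = F.conv3x3_forward(x, W + dW_dir, b)
        assert ((y2 - y0) * u).sum() == pytest.approx((dW_dir * dW).sum(), rel=1e-10)

    def test_maxpool_and_upsample_adjoints(self, rng):
        from cardioseg.nn.layers import BilinearUp2, MaxPool2, TransposeUp2
        xp = rng.normal(size=(2, 3, 8, 8))
        mp = MaxPool2()
        y0 = mp.forward(xp, training=True)
        u = rng.normal(size=y0.shape)
        dxT = mp.backward(u)
        eps = 1e-7  # keep argmax pattern fixed
        d = rng.normal(size=xp.shape) * eps
        y1 = MaxPool2().forward(xp + d, training=True)
        assert ((y1 - y0) * u).sum() / eps == pytest.approx(
            (d * dxT).sum() / eps, rel=1e-5)
        for cls in (TransposeUp2, BilinearUp2):
            up = cls(3, 2, rng)
            xt = rng.normal(size=(2, 3, 5, 5))
            ut = rng.normal(size=(2, 2, 10, 10))
            y0 = up.forward(xt, training=True)
            dxT = up.backward(ut)
            dt = rng.normal(size=xt.shape)
            y1 = up.forward(xt + dt, training=True)
            assert ((y1 - y0) * ut).sum() == pytest.approx(
                (dt * dxT).sum(), rel=1e-4)


class TestCheckpoint:
    def test_round_trip_preserves_predictions_and_running_stats(self, rng, tmp_path):
        net = build_network(NetworkConfig(depth=2, base_channels=4, input_size=16))
        # perturb running stats so the round trip is nontrivial
        for bn in net.bn_layers():
            bn.bn.running_mean += rng.normal(size=bn.bn.running_mean.shape).astype(np.float32)
        x = rng.normal(size=(2, 16, 16)).astype(np.float32)
        before = forward(net, x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net)
        restored = load_checkpoint(path)
        assert np.array_equal(forward(restored, x), before)
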