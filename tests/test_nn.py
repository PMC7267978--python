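"""The NumPy NN engine against brute-force and finite-difference oracles."""

import numpy as np
import pytest

from fmridecoder.nn import (
    Adam,
    BatchNorm3d,
    Conv3d,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
    cross_entropy,
    softmax,
)

RNG = np.random.default_rng(42)


def naive_conv3d(x, W, b, stride, padding):
    """Direct-loop 3D cross-correlation oracle."""
    n, cin, D, H, Wd = x.shape
    cout, _, kd, kh, kw = W.shape
    s0, s1, s2 = stride
    p0, p1, p2 = padding
    xp = np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
    Do = (D + 2 * p0 - kd) // s0 + 1
    Ho = (H + 2 * p1 - kh) // s1 + 1
    Wo = (Wd + 2 * p2 - kw) // s2 + 1
    y = np.zeros((n, cout, Do, Ho, Wo))
    for i in range(n):
        for o in range(cout):
            for a in range(Do):
                for bb in range(Ho):
                    for c in range(Wo):
                        patch = xp[i, :, a * s0:a * s0 + kd,
                                   bb * s1:bb * s1 + kh, c * s2:c * s2 + kw]
                        y[i, o, a, bb, c] = (patch * W[o]).sum()
            if b is not None:
                y[i, o] += b[o]
    return y


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestConv3d:
    @pytest.mark.parametrize("stride,padding,bias", [
        (1, 0, True), (2, 1, True), ((1, 2, 1), (1, 0, 1), False)])
    def test_forward_matches_naive_oracle(self, stride, padding, bias):
        conv = Conv3d(2, 3, 3, stride=stride, padding=padding, bias=bias,
                      dtype=np.float64)
        conv.initialize(np.random.default_rng(0))
        x = RNG.standard_normal((2, 2, 5, 6, 7))
        y = conv.forward(x)
        expect = naive_conv3d(x, conv.W.value,
                              None if conv.b is None else conv.b.value,
                              conv.stride, conv.padding)
        assert y.shape == expect.shape
        assert np.allclose(y, expect, atol=1e-10)

    def test_pointwise_forward_matches_naive_oracle(self):
        conv = Conv3d(4, 2, 1, dtype=np.float64)
        conv.initialize(np.random.default_rng(1))
        x = RNG.standard_normal((3, 4, 3, 3, 3))
        assert np.allclose(conv.forward(x),
                           naive_conv3d(x, conv.W.value, conv.b.value,
                                        conv.stride, conv.padding), atol=1e-12)

    @pytest.mark.parametrize("stride,padding", [(1, 1), (2, 1), (1, 0)])
    def test_backward_matches_finite_differences(self, stride, padding):
        conv = Conv3d(2, 3, 3, stride=stride, padding=padding, dtype=np.float64)
        conv.initialize(np.random.default_rng(2))
        x = RNG.standard_normal((2, 2, 4, 5, 4))
        gy = RNG.standard_normal(conv.forward(x).shape)

        def loss():
            return float((conv.forward(x) * gy).sum())

        conv.W.grad[...] = 0
        conv.b.grad[...] = 0
        conv.forward(x)
        gx = conv.backward(gy)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-6)
        assert np.allclose(conv.W.grad, numeric_grad(loss, conv.W.value), atol=1e-6)
        assert np.allclose(conv.b.grad, numeric_grad(loss, conv.b.value), atol=1e-6)

    def test_too_small_input_raises(self):
        conv = Conv3d(1, 1, 3)
        with pytest.raises(ValueError):
            conv.forward(np.zeros((1, 1, 2, 2, 2)))


class TestBatchNorm:
    def test_train_output_is_standardized(self):
        bn = BatchNorm3d(3)
        x = RNG.standard_normal((4, 3, 2, 2, 2)) * 5 + 2
        y = bn.forward(x, mode="train")
        assert np.allclose(y.mean(axis=(0, 2, 3, 4)), 0, atol=1e-5)
        assert np.allclose(y.std(axis=(0, 2, 3, 4)), 1, atol=1e-2)

    def test_running_stats_are_cumulative_means(self):
        bn = BatchNorm3d(1)
        batches = [RNG.standard_normal((2, 1, 2, 2, 2)) + i for i in range(3)]
        for b in batches:
            bn.forward(b, mode="train")
        means = [b.mean() for b in batches]
        assert bn.running_mean[0] == pytest.approx(np.mean(means), abs=1e-6)

    def test_train_backward_matches_finite_differences(self):
        bn = BatchNorm3d(2, dtype=np.float64)
        bn.gamma.value = RNG.standard_normal(2)
        bn.beta.value = RNG.standard_normal(2)
        x = RNG.standard_normal((3, 2, 2, 2, 2))
        gy = RNG.standard_normal(x.shape)

        def loss():
            return float((bn.forward(x, mode="train") * gy).sum())

        bn.forward(x, mode="train")
        gx = bn.backward(gy)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-6)

    def test_eval_uses_frozen_statistics(self):
        bn = BatchNorm3d(1)
        bn.forward(RNG.standard_normal((4, 1, 2, 2, 2)), mode="train")
        x = RNG.standard_normal((2, 1, 2, 2, 2))
        y1 = bn.forward(x, mode="eval")
        y2 = bn.forward(x, mode="eval")
        assert np.array_equal(y1, y2)


class TestReLUGuidance:
    def test_plain_backward_gates_on_forward_sign(self):
        r = ReLU()
        x = np.array([[-1.0, 2.0, -3.0, 4.0]])
        g = np.array([[1.0, -1.0, 1.0, -1.0]])
        r.forward(x)
        assert np.array_equal(r.backward(g), [[0.0, -1.0, 0.0, -1.0]])

    def test_guided_backward_gates_on_both_signs(self):
        r = ReLU()
        x = np.array([[-1.0, 2.0, -3.0, 4.0]])
        g = np.array([[1.0, -1.0, 1.0, 1.0]])
        r.forward(x)
        # passes only where forward input > 0 AND incoming gradient > 0
        assert np.array_equal(r.backward(g, guided=True), [[0.0, 0.0, 0.0, 1.0]])


class TestLinearAndLoss:
    def test_linear_backward_matches_finite_differences(self):
        lin = Linear(4, 3, dtype=np.float64)
        lin.initialize(np.random.default_rng(3))
        x = RNG.standard_normal((5, 4))
        gy = RNG.standard_normal((5, 3))

        def loss():
            return float((lin.forward(x) * gy).sum())

        lin.forward(x)
        gx = lin.backward(gy)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-7)
        assert np.allclose(lin.W.grad, numeric_grad(loss, lin.W.value), atol=1e-7)

    def test_softmax_rows_sum_to_one_and_shift_invariant(self):
        z = RNG.standard_normal((4, 6))
        p = softmax(z)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.allclose(p, softmax(z + 100.0))

    def test_cross_entropy_matches_log_softmax(self):
        from scipy.special import log_softmax

        z = RNG.standard_normal((5, 3))
        y = np.array([0, 2, 1, 1, 0])
        loss, grad = cross_entropy(z, y)
        expect = -log_softmax(z, axis=1)[np.arange(5), y].mean()
        assert loss == pytest.approx(expect, abs=1e-6)
        assert np.allclose(grad, numeric_grad_logits(z, y), atol=1e-6)


def numeric_grad_logits(z, y, eps=1e-6):
    g = np.zeros_like(z)
    for i in np.ndindex(z.shape):
        zp = z.copy(); zp[i] += eps
        zm = z.copy(); zm[i] -= eps
        g[i] = (cross_entropy(zp, y)[0] - cross_entropy(zm, y)[0]) / (2 * eps)
    return g


class TestResidualBlock:
    def _block(self):
        main = Sequential(Conv3d(2, 3, 3, stride=2, padding=1, bias=False,
                                 dtype=np.float64))
        short = Sequential(Conv3d(2, 3, 3, stride=2, padding=1, dtype=np.float64))
        block = ResidualBlock(main, short)
        block.initialize(np.random.default_rng(4))
        return block

    def test_backward_matches_finite_differences(self):
        block = self._block()
        x = RNG.standard_normal((2, 2, 4, 4, 4))
        gy = RNG.standard_normal(block.forward(x).shape)

        def loss():
            return float((block.forward(x) * gy).sum())

        block.forward(x)
        gx = block.backward(gy)
        assert np.allclose(gx, numeric_grad(loss, x), atol=1e-6)

    def test_identity_shortcut_when_shapes_match(self):
        main = Sequential(Conv3d(2, 2, 3, padding=1, dtype=np.float64))
        block = ResidualBlock(main, None)
        block.initialize(np.random.default_rng(5))
        x = RNG.standard_normal((1, 2, 3, 3, 3))
        h = block.main.forward(x)
        assert np.allclose(block.forward(x), np.maximum(h + x, 0))


class TestAdam:
    def test_first_step_is_signed_lr(self):
        # with bias correction, the first update is -lr * g/(|g| + ~eps)
        from fmridecoder.nn import Param

        p = Param(np.array([1.0, -1.0]))
        p.grad = np.array([0.5, -0.25])
        opt = Adam([p], lr=0.1)
        opt.step()
        assert np.allclose(p.value, [1.0 - 0.1, -1.0 + 0.1], atol=1e-6)

    def test_zero_grad_clears_accumulators(self):
        from fmridecoder.nn import Param

        p = Param(np.ones(3))
        p.grad += 5.0
        Adam([p]).zero_grad()
        assert np.array_equal(p.grad, np.zeros(3))
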