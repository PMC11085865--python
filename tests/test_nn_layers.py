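"""Operator-level network tests: brute-force oracles, structural
independence, gradient checks."""

import numpy as np
import pytest

from tetcad.nn.layers import (
    BatchNorm2d,
    Dense,
    DepthwiseConv2d,
    GlobalAvgPool,
    GroupedPointwise,
    MaxPool2d,
    ReLU,
    cross_entropy,
    softmax,
)


def depthwise_oracle(x, w, stride, pad):
    """Direct four-nested-loop evaluation of the per-channel convolution."""
    n, h, wd, c = x.shape
    dk = w.shape[0]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    ho = (h + 2 * pad - dk) // stride + 1
    wo = (wd + 2 * pad - dk) // stride + 1
    out = np.zeros((n, ho, wo, c))
    for nn in range(n):
        for y in range(ho):
            for xx in range(wo):
                for m in range(c):
                    acc = 0.0
                    for i in range(dk):
                        for j in range(dk):
                            acc += w[i, j, m] * xp[nn, y * stride + i, xx * stride + j, m]
                    out[nn, y, xx, m] = acc
    return out


def grouped_oracle(x, w):
    """Per-pixel, per-group matrix product evaluated by explicit loops."""
    n, h, wd, c = x.shape
    g, cin, cout = w.shape
    out = np.zeros((n, h, wd, g * cout))
    for nn in range(n):
        for y in range(h):
            for xx in range(wd):
                for k in range(g):
                    out[nn, y, xx, k * cout:(k + 1) * cout] = (
                        x[nn, y, xx, k * cin:(k + 1) * cin] @ w[k]
                    )
    return out


class TestIntraStateOperator:
    def test_matches_loop_oracle_on_random_instances(self):
        # 50 random small instances against the brute-force evaluation
        for trial in range(50):
            rng = np.random.default_rng(trial)
            c = int(rng.integers(1, 5))
            dk = int(rng.choice([1, 3, 5]))
            stride = int(rng.choice([1, 2]))
            h, w = int(rng.integers(dk, 9)), int(rng.integers(dk, 9))
            layer = DepthwiseConv2d(c, dk, stride=stride, rng=rng, bias=False)
            x = rng.normal(size=(2, h, w, c)).astype(np.float32)
            got = layer.forward(x)
            want = depthwise_oracle(x, layer.weight.value, stride, dk // 2)
            np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-5)

    def test_delta_kernel_is_identity(self, rng):
        c, dk = 3, 3
        layer = DepthwiseConv2d(c, dk, stride=1, rng=rng, bias=False)
        layer.weight.value[...] = 0.0
        layer.weight.value[dk // 2, dk // 2, :] = 1.0
        x = rng.normal(size=(2, 6, 7, c)).astype(np.float32)
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-6)

    def test_no_cross_channel_mixing(self, rng):
        layer = DepthwiseConv2d(4, 3, rng=rng)
        x = rng.normal(size=(1, 8, 8, 4)).astype(np.float32)
        base = layer.forward(x)
        x2 = x.copy()
        x2[..., 1] += rng.normal(size=(1, 8, 8))
        out2 = layer.forward(x2)
        np.testing.assert_array_equal(base[..., 0], out2[..., 0])
        np.testing.assert_array_equal(base[..., 2:], out2[..., 2:])
        assert np.any(base[..., 1] != out2[..., 1])

    def test_filter_count_mismatch_raises(self, rng):
        layer = DepthwiseConv2d(4, 3, rng=rng)
        with pytest.raises(ValueError, match="channels"):
            layer.forward(np.zeros((1, 5, 5, 3), np.float32))


class TestInterStateOperator:
    def test_matches_matmul_oracle_on_random_instances(self):
        for trial in range(50):
            rng = np.random.default_rng(1000 + trial)
            g = int(rng.choice([1, 2, 3, 6]))
            cin_g = int(rng.integers(1, 4))
            cout_g = int(rng.integers(1, 4))
            layer = GroupedPointwise(g * cin_g, g * cout_g, groups=g, rng=rng, bias=False)
            x = rng.normal(size=(2, 3, 2, g * cin_g)).astype(np.float32)
            np.testing.assert_allclose(
                layer.forward(x), grouped_oracle(x, layer.weight.value),
                rtol=1e-5, atol=1e-5)

    def test_identity_matrices_pass_through(self, rng):
        layer = GroupedPointwise(6, 6, groups=3, rng=rng, bias=False)
        layer.weight.value[...] = np.eye(2)
        x = rng.normal(size=(2, 4, 4, 6)).astype(np.float32)
        np.testing.assert_allclose(layer.forward(x), x, atol=1e-6)

    def test_block_diagonal_no_cross_group_mixing(self, rng):
        layer = GroupedPointwise(9, 9, groups=3, rng=rng)
        x = rng.normal(size=(1, 4, 4, 9)).astype(np.float32)
        base = layer.forward(x)
        x2 = x.copy()
        x2[..., 6:9] += 1.0  # perturb group 2 only
        out2 = layer.forward(x2)
        np.testing.assert_array_equal(base[..., :6], out2[..., :6])
        assert np.any(base[..., 6:] != out2[..., 6:])

    def test_single_group_equals_dense_mixing(self, rng):
        layer = GroupedPointwise(5, 7, groups=1, rng=rng, bias=False)
        x = rng.normal(size=(2, 3, 3, 5)).astype(np.float32)
        dense = x.reshape(-1, 5) @ layer.weight.value[0]
        np.testing.assert_allclose(
            layer.forward(x).reshape(-1, 7), dense, rtol=1e-5, atol=1e-6)

    def test_divisibility_enforced(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            GroupedPointwise(10, 10, groups=3, rng=rng)


class TestSupportLayers:
    def test_maxpool_matches_naive_windows(self, rng):
        pool = MaxPool2d(k=3, stride=2, pad=1)
        x = rng.normal(size=(1, 7, 7, 2)).astype(np.float32)
        out = pool.forward(x)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        for y in range(out.shape[1]):
            for xx in range(out.shape[2]):
                window = xp[0, 2 * y:2 * y + 3, 2 * xx:2 * xx + 3, :]
                np.testing.assert_array_equal(out[0, y, xx], window.max(axis=(0, 1)))

    def test_batchnorm_normalizes_batch_statistics(self, rng):
        bn = BatchNorm2d(3)
        x = rng.normal(2.0, 3.0, size=(4, 5, 5, 3)).astype(np.float32)
        out = bn.forward(x, training=True)
        np.testing.assert_allclose(out.mean(axis=(0, 1, 2)), 0.0, atol=1e-5)
        np.testing.assert_allclose(out.std(axis=(0, 1, 2)), 1.0, atol=1e-3)

    def test_global_avg_pool(self, rng):
        gap = GlobalAvgPool()
        x = rng.normal(size=(2, 4, 6, 3)).astype(np.float32)
        np.testing.assert_allclose(gap.forward(x), x.mean(axis=(1, 2)), rtol=1e-6)


class TestGradients:
    def _mini_block(self, rng):
        return [
            DepthwiseConv2d(6, 3, stride=1, rng=rng), BatchNorm2d(6), ReLU(),
            GroupedPointwise(6, 6, groups=3, rng=rng), BatchNorm2d(6), ReLU(),
            GroupedPointwise(6, 8, groups=1, rng=rng), BatchNorm2d(8), ReLU(),
            MaxPool2d(), GlobalAvgPool(), Dense(8, 2, rng=rng),
        ]

    def test_backprop_matches_finite_differences_through_block(self):
        rng = np.random.default_rng(0)
        layers = self._mini_block(rng)

        def loss_of(x):
            out = x
            for layer in layers:
                out = layer.forward(out, training=True)
            p = softmax(out)
            y = np.zeros_like(p)
            y[:, 1] = 1.0
            return float(-(y * np.log(p)).sum() / len(p))

        x0 = rng.normal(size=(3, 8, 8, 6))
        out = x0
        for layer in layers:
            out = layer.forward(out, training=True)
        p = softmax(out)
        y = np.zeros_like(p)
        y[:, 1] = 1.0
        grad = (p - y) / len(p)
        for layer in reversed(layers):
            grad = layer.backward(grad)

        eps = 1e-6
        for idx in [(0, 1, 2, 3), (1, 4, 5, 0), (2, 7, 0, 5)]:
            xp = x0.copy(); xp[idx] += eps
            xm = x0.copy(); xm[idx] -= eps
            numeric = (loss_of(xp) - loss_of(xm)) / (2 * eps)
            assert abs(numeric - grad[idx]) <= 1e-4 * max(abs(numeric), 1e-3)

    def test_weight_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        layers = self._mini_block(rng)

        def loss_of(x):
            out = x
            for layer in layers:
                out = layer.forward(out, training=True)
            p = softmax(out)
            y = np.zeros_like(p)
            y[:, 0] = 1.0
            return float(-(y * np.log(p)).sum() / len(p))

        x0 = rng.normal(size=(2, 8, 8, 6))
        out = x0
        for layer in layers:
            out = layer.forward(out, training=True)
        p = softmax(out)
        y = np.zeros_like(p)
        y[:, 0] = 1.0
        grad = (p - y) / len(p)
        for layer in reversed(layers):
            grad = layer.backward(grad)

        param = layers[3].weight  # inter-state stage weights
        eps = 1e-5
        orig = float(param.value[1, 0, 1])
        hi = np.float32(orig + eps)
        lo = np.float32(orig - eps)
        param.value[1, 0, 1] = hi
        lp = loss_of(x0)
        param.value[1, 0, 1] = lo
        lm = loss_of(x0)
        param.value[1, 0, 1] = orig
        numeric = (lp - lm) / (float(hi) - float(lo))  # realized float32 step
        assert abs(numeric - param.grad[1, 0, 1]) <= 1e-3 * max(abs(numeric), 1e-3)


class TestLossClosedForms:
    def test_perfect_predictions_have_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_give_ln2(self):
        probs = np.full((4, 2), 0.5)
        assert cross_entropy(probs, np.array([0, 1, 0, 1])) == pytest.approx(np.log(2), rel=1e-9)

    def test_hand_computed_two_sample_loss(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        expected = -(np.log(0.9) + np.log(0.8)) / 2
        assert cross_entropy(probs, np.array([0, 1])) == pytest.approx(expected, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_entropy(np.zeros((0, 2)), np.zeros((0,)))

    def test_softmax_rows_sum_to_one(self, rng):
        logits = rng.normal(scale=20, size=(8, 2))
        np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-6)
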