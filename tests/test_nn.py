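"""Gradient and contract checks for the autograd/layers core."""

import numpy as np
import pytest

from msatnet.nn import (
    Adam,
    AvgPool1d,
    BatchNorm,
    Conv1d,
    Linear,
    Parameter,
    Tensor,
    max_norm_rescale,
    no_grad,
)
from msatnet.nn.functional import (
    avg_pool1d,
    batch_norm_train,
    conv1d,
    dropout,
    log_softmax,
    softmax,
    spatial_collapse,
)


def numerical_grad(f, arr, eps=1e-5):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = arr[i]
        arr[i] = orig + eps
        fp = f()
        arr[i] = orig - eps
        fm = f()
        arr[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g


def half_sq_sum(t):
    return (t * t).sum() * 0.5


class TestConv1d:
    def test_gradients_match_finite_differences(self, rng):
        x = Parameter(rng.normal(size=(2, 3, 12)))
        w = Parameter(rng.normal(size=(4, 3, 3)))
        b = Parameter(rng.normal(size=4))

        def value():
            out = conv1d(Tensor(x.data), Tensor(w.data), Tensor(b.data), dilation=2, pad_left=4)
            return float((out.data**2).sum() / 2)

        half_sq_sum(conv1d(x, w, b, dilation=2, pad_left=4)).backward()
        for p in (x, w, b):
            assert np.abs(p.grad - numerical_grad(value, p.data)).max() < 1e-6

    def test_same_padding_preserves_length(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 50)))
        layer = Conv1d(2, 5, 7, padding="same", rng=rng)
        assert layer(x).shape == (1, 5, 50)

    def test_causal_padding_never_sees_future(self, rng):
        layer = Conv1d(1, 1, 3, dilation=2, padding="causal", rng=rng)
        x = rng.normal(size=(1, 1, 20)).astype(np.float32)
        base = layer(Tensor(x)).data.copy()
        x2 = x.copy()
        x2[0, 0, 10:] += 5.0
        pert = layer(Tensor(x2)).data
        np.testing.assert_array_equal(base[0, 0, :10], pert[0, 0, :10])

    def test_channel_mismatch_raises(self, rng):
        layer = Conv1d(3, 4, 5, rng=rng)
        with pytest.raises(ValueError, match="channel"):
            layer(Tensor(rng.normal(size=(1, 2, 30))))

    def test_too_short_input_raises(self, rng):
        with pytest.raises(ValueError, match="too short"):
            conv1d(Tensor(rng.normal(size=(1, 1, 3))), Tensor(rng.normal(size=(1, 1, 5))))


class TestPooling:
    @pytest.mark.parametrize("length,stride", [(4, 4), (3, 2), (5, 1)])
    def test_matches_manual_windows(self, rng, length, stride):
        x = rng.normal(size=(2, 3, 17))
        out = avg_pool1d(Tensor(x), length, stride).data
        T_out = (17 - length) // stride + 1
        expected = np.stack(
            [x[..., s * stride : s * stride + length].mean(-1) for s in range(T_out)], axis=-1
        )
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_gradient(self, rng):
        x = Parameter(rng.normal(size=(2, 2, 13)))

        def value():
            return float((avg_pool1d(Tensor(x.data), 3, 2).data ** 2).sum() / 2)

        half_sq_sum(avg_pool1d(x, 3, 2)).backward()
        assert np.abs(x.grad - numerical_grad(value, x.data)).max() < 1e-7


class TestSpatialCollapse:
    def test_matches_einsum(self, rng):
        x = rng.normal(size=(2, 4, 3, 9))
        w = rng.normal(size=(4, 2, 3))
        out = spatial_collapse(Tensor(x), Tensor(w)).data
        expected = np.einsum("bfct,fmc->bfmt", x, w).reshape(2, 8, 9)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_gradients(self, rng):
        x = Parameter(rng.normal(size=(2, 3, 4, 5)))
        w = Parameter(rng.normal(size=(3, 2, 4)))

        def value():
            return float((spatial_collapse(Tensor(x.data), Tensor(w.data)).data ** 2).sum() / 2)

        half_sq_sum(spatial_collapse(x, w)).backward()
        for p in (x, w):
            assert np.abs(p.grad - numerical_grad(value, p.data)).max() < 1e-6


class TestBatchNorm:
    def test_train_normalizes(self, rng):
        bn = BatchNorm(4)
        x = Tensor(rng.normal(loc=3.0, scale=2.0, size=(16, 4, 10)))
        out = bn(x).data
        assert np.abs(out.mean(axis=(0, 2))).max() < 1e-6
        assert np.abs(out.std(axis=(0, 2)) - 1).max() < 1e-2

    def test_gradients(self, rng):
        x = Parameter(rng.normal(size=(5, 3, 4)))
        gamma = Parameter(rng.normal(size=(1, 3, 1)))
        beta = Parameter(rng.normal(size=(1, 3, 1)))

        def value():
            out, _, _ = batch_norm_train(
                Tensor(x.data), Tensor(gamma.data), Tensor(beta.data), (0, 2), 1e-3
            )
            return float((out.data**2).sum() / 2)

        out, _, _ = batch_norm_train(x, gamma, beta, (0, 2), 1e-3)
        half_sq_sum(out).backward()
        for p in (x, gamma, beta):
            assert np.abs(p.grad - numerical_grad(value, p.data)).max() < 1e-5

    def test_eval_uses_running_stats(self, rng):
        bn = BatchNorm(2)
        x = rng.normal(size=(32, 2, 8))
        for _ in range(300):
            bn(Tensor(x))
        bn.eval()
        out = bn(Tensor(x)).data
        assert np.abs(out.mean(axis=(0, 2))).max() < 0.1


class TestSoftmax:
    def test_rows_sum_to_one(self, rng):
        s = softmax(Tensor(rng.normal(size=(7, 5)) * 30), axis=-1).data
        np.testing.assert_allclose(s.sum(-1), 1.0, atol=1e-6)
        assert (s >= 0).all()

    def test_log_softmax_consistent(self, rng):
        x = Tensor(rng.normal(size=(4, 6)))
        np.testing.assert_allclose(
            log_softmax(x).data, np.log(softmax(x).data), atol=1e-8
        )

    def test_matmul_gradient(self, rng):
        a = Parameter(rng.normal(size=(3, 4)))
        b = Parameter(rng.normal(size=(4, 2)))

        def value():
            return float(((a.data @ b.data) ** 2).sum() / 2)

        half_sq_sum(a @ b).backward()
        for p in (a, b):
            assert np.abs(p.grad - numerical_grad(value, p.data)).max() < 1e-7


class TestDropout:
    def test_identity_at_inference(self, rng):
        x = Tensor(rng.normal(size=(5, 5)))
        out = dropout(x, 0.5, rng, training=False)
        assert out is x

    def test_scaling_preserves_mean(self):
        gen = np.random.default_rng(0)
        x = Tensor(np.ones((200, 200)))
        out = dropout(x, 0.3, gen, training=True).data
        assert abs(out.mean() - 1.0) < 0.02


class TestOptim:
    def test_adam_descends_quadratic(self):
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            loss = half_sq_sum(p)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2

    def test_frozen_parameter_is_skipped(self):
        p = Parameter(np.array([1.0]))
        p.trainable = False
        opt = Adam([p], lr=0.5)
        half_sq_sum(p).backward()
        opt.step()
        assert p.data[0] == 1.0

    def test_max_norm_inside_ball_unchanged(self):
        w = np.array([[0.06], [0.08]])  # norm 0.1
        np.testing.assert_array_equal(max_norm_rescale(w, 0.25), w)

    def test_max_norm_rescales_to_bound(self):
        w = np.array([[3.0], [4.0]])
        out = max_norm_rescale(w, 0.25)
        np.testing.assert_allclose(out[:, 0], [0.15, 0.20], rtol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(out), 0.25, rtol=1e-12)


class TestAutogradMisc:
    def test_no_grad_blocks_graph(self):
        p = Parameter(np.ones(3))
        with no_grad():
            out = (p * 2.0).sum()
        assert not out.requires_grad

    def test_broadcast_add_gradient(self, rng):
        a = Parameter(rng.normal(size=(3, 4)))
        b = Parameter(rng.normal(size=(4,)))

        def value():
            return float(((a.data + b.data) ** 2).sum() / 2)

        half_sq_sum(a + b).backward()
        for p in (a, b):
            assert np.abs(p.grad - numerical_grad(value, p.data)).max() < 1e-7

    def test_linear_layer_shapes(self, rng):
        lin = Linear(5, 3, rng=rng)
        out = lin(Tensor(rng.normal(size=(7, 5))))
        assert out.shape == (7, 3)
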