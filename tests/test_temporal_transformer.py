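import numpy as np
import pytest

from msatnet.nn import Tensor, no_grad
from msatnet.temporal_transformer import (
    ATT,
    MultiHeadAttention,
    TemporalDecoder,
    TemporalDecoderConfig,
    dilated_causal_conv,
    empirical_receptive_field,
    multi_head_attention,
    receptive_field,
)

GRID = [
    TemporalDecoderConfig(n_blocks=n, layers_per_block=m, kernel_length=K, dilation_base=b,
                          n_filters=3, dropout_p=0.0)
    for m in (1, 2)
    for K in (2, 4)
    for b in (2, 3)
    for n in (1, 2)
]


def brute_force_dilated(x, f, d):
    """Direct summation oracle: out[t] = sum_i f[i] x[t - d i]."""
    n, k = len(x), len(f)
    out = np.zeros(n)
    for t in range(n):
        for i in range(k):
            j = t - d * i
            if j >= 0:
                out[t] += f[i] * x[j]
    return out


class TestDilatedCausalConv:
    def test_identity_kernel(self):
        np.testing.assert_array_equal(
            dilated_causal_conv([1, 0, 0, 0], [1.0], 1), [1, 0, 0, 0]
        )

    def test_hand_evaluated_example(self):
        # out[t] = x[t] + x[t-2], zero padded
        np.testing.assert_array_equal(
            dilated_causal_conv([1, 2, 3, 4], [1, 1], 2), [1, 2, 4, 6]
        )

    @pytest.mark.parametrize("d,k,n", [(1, 3, 10), (2, 2, 8), (3, 4, 20)])
    def test_matches_brute_force(self, rng, d, k, n):
        x = rng.normal(size=n)
        f = rng.normal(size=k)
        np.testing.assert_allclose(
            dilated_causal_conv(x, f, d), brute_force_dilated(x, f, d), atol=1e-12
        )

    @pytest.mark.parametrize("p", [0, 3, 7])
    def test_impulse_response_support(self, p):
        n, k, d = 16, 3, 2
        x = np.zeros(n)
        x[p] = 1.0
        out = dilated_causal_conv(x, np.ones(k), d)
        support = set(np.flatnonzero(out))
        expected = {p + d * i for i in range(k) if p + d * i < n}
        assert support == expected

    def test_invalid_dilation(self):
        with pytest.raises(ValueError, match="dilation"):
            dilated_causal_conv([1.0], [1.0], 0)


class TestReceptiveField:
    def test_kernel_one_sees_one_sample(self):
        cfg = TemporalDecoderConfig(n_blocks=3, layers_per_block=2, kernel_length=1)
        assert receptive_field(cfg) == 1

    def test_reference_settings_give_19(self):
        cfg = TemporalDecoderConfig(n_blocks=2, layers_per_block=2, kernel_length=4,
                                    dilation_base=2)
        assert receptive_field(cfg) == 19

    def test_single_small_conv(self):
        cfg = TemporalDecoderConfig(n_blocks=1, layers_per_block=1, kernel_length=2)
        assert receptive_field(cfg) == 2

    def test_monotone_in_each_argument(self):
        base = dict(n_blocks=2, layers_per_block=2, kernel_length=4, dilation_base=2)
        r0 = receptive_field(TemporalDecoderConfig(**base))
        for key in ("n_blocks", "layers_per_block", "kernel_length"):
            bigger = dict(base)
            bigger[key] += 1
            assert receptive_field(TemporalDecoderConfig(**bigger)) > r0

    @pytest.mark.parametrize("cfg", GRID)
    def test_formula_matches_empirical_probe(self, cfg):
        decoder = TemporalDecoder(cfg, rng=np.random.default_rng(7))
        r = receptive_field(cfg)
        t = r + 3  # deep enough that the full field fits
        assert empirical_receptive_field(decoder, t) == r

    def test_probe_at_time_zero(self):
        cfg = TemporalDecoderConfig(n_filters=3, dropout_p=0.0)
        decoder = TemporalDecoder(cfg, rng=np.random.default_rng(0))
        assert empirical_receptive_field(decoder, 0) == 1

    def test_probe_truncated_by_sequence_start(self):
        cfg = TemporalDecoderConfig(n_filters=3, dropout_p=0.0)  # r = 19
        decoder = TemporalDecoder(cfg, rng=np.random.default_rng(0))
        t = 10
        assert empirical_receptive_field(decoder, t) == t + 1


class TestDecoder:
    def test_preserves_shape(self, rng):
        cfg = TemporalDecoderConfig(n_filters=4, dropout_p=0.0)
        dec = TemporalDecoder(cfg, rng=rng)
        dec.eval()
        with no_grad():
            out = dec(Tensor(rng.normal(size=(2, 4, 30)).astype(np.float32)))
        assert out.shape == (2, 4, 30)

    @pytest.mark.parametrize("cfg", GRID)
    def test_causality_exact(self, cfg):
        dec = TemporalDecoder(cfg, rng=np.random.default_rng(3))
        dec.eval()
        gen = np.random.default_rng(11)
        x = gen.normal(size=(1, cfg.n_filters, 40)).astype(np.float32)
        t0 = 17
        x2 = x.copy()
        x2[:, :, t0:] += gen.normal(size=(1, cfg.n_filters, 40 - t0))
        with no_grad():
            a = dec(Tensor(x)).data
            b = dec(Tensor(x2)).data
        np.testing.assert_array_equal(a[:, :, :t0], b[:, :, :t0])

    def test_zero_input_zero_output(self, rng):
        cfg = TemporalDecoderConfig(n_filters=4, dropout_p=0.0)
        dec = TemporalDecoder(cfg, rng=rng)
        dec.eval()
        with no_grad():
            out = dec(Tensor(np.zeros((1, 4, 25), dtype=np.float32)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-7)

    def test_feature_mismatch_raises(self, rng):
        dec = TemporalDecoder(TemporalDecoderConfig(n_filters=4), rng=rng)
        with pytest.raises(ValueError, match="features"):
            dec(Tensor(rng.normal(size=(1, 3, 25))))

    def test_linearized_single_layer_matches_reference_conv(self):
        """1-feature, 1-block, 1-layer decoder (linear probe mode) equals the
        reference dilated causal convolution plus the identity residual."""
        cfg = TemporalDecoderConfig(
            n_blocks=1, layers_per_block=1, kernel_length=2, dilation_base=2,
            n_filters=1, dropout_p=0.0,
        )
        dec = TemporalDecoder(cfg, rng=np.random.default_rng(5))
        gen = np.random.default_rng(9)
        x = gen.normal(size=12)
        kernel = dec.blocks[0].convs[0].weight.data[0, 0, :]  # [K], taps oldest-first
        with no_grad():
            out = dec(Tensor(x[None, None, :].astype(np.float64)), linear=True).data[0, 0]
        # cross-correlation with causal left-padding: tap k sees x[t - (K-1-k)*d]
        expected = dilated_causal_conv(x, kernel[::-1], d=1) + x
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestMultiHeadAttention:
    @staticmethod
    def brute_force(X, mha):
        """Element-wise reimplementation with explicit loops."""
        N, d = X.shape
        H, dk = mha.n_heads, mha.d_k
        heads = []
        for h in range(H):
            Q = X @ mha.W_Q[h].data
            K = X @ mha.W_K[h].data
            V = X @ mha.W_V[h].data
            Z = np.zeros((N, dk))
            for i in range(N):
                scores = np.array(
                    [sum(Q[i, a] * K[j, a] for a in range(dk)) / np.sqrt(dk) for j in range(N)]
                )
                e = np.exp(scores - scores.max())
                A = e / e.sum()
                for j in range(N):
                    Z[i] += A[j] * V[j]
            heads.append(Z)
        return np.concatenate(heads, axis=1) @ mha.W_O.data

    def test_single_timestep_attention_is_identity_weight(self, rng):
        mha = MultiHeadAttention(4, 2, rng=rng)
        X = rng.normal(size=(1, 4))
        for A in mha.attention_weights(X):
            np.testing.assert_allclose(A, [[1.0]], atol=1e-12)

    def test_zero_output_projection(self, rng):
        mha = MultiHeadAttention(4, 2, rng=rng)
        mha.W_O.data = np.zeros_like(mha.W_O.data)
        out = mha(Tensor(rng.normal(size=(5, 4)))).data
        np.testing.assert_array_equal(out, np.zeros((5, 4)))

    @pytest.mark.parametrize("case", range(20))
    def test_matches_brute_force(self, case):
        gen = np.random.default_rng(100 + case)
        H = [1, 2][case % 2]
        d = H * int(gen.integers(1, 5))
        N = int(gen.integers(1, 9))
        mha = MultiHeadAttention(d, H, rng=gen)
        X = gen.normal(size=(N, d))
        with no_grad():
            out = mha(Tensor(X)).data
        np.testing.assert_allclose(out, self.brute_force(X, mha), atol=1e-6)

    def test_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(8, 2, rng=rng)
        X = rng.normal(size=(7, 8)) * 10
        for A in mha.attention_weights(X):
            np.testing.assert_allclose(A.sum(axis=-1), 1.0, atol=1e-6)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            MultiHeadAttention(5, 2, rng=rng)

    def test_functional_alias(self, rng):
        mha = MultiHeadAttention(4, 2, rng=rng)
        X = rng.normal(size=(3, 4))
        with no_grad():
            np.testing.assert_array_equal(
                multi_head_attention(X, mha).data, mha(Tensor(X)).data
            )

    def test_per_head_equals_fused_layout(self, rng):
        """H per-head [d, d/H] projections match one fused [d, d] map."""
        mha = MultiHeadAttention(6, 2, rng=rng)
        X = rng.normal(size=(5, 6))
        Wq_fused = np.concatenate([w.data for w in mha.W_Q], axis=1)
        Q_fused = X @ Wq_fused
        for h in range(2):
            np.testing.assert_allclose(Q_fused[:, 3 * h : 3 * (h + 1)], X @ mha.W_Q[h].data)


class TestATT:
    def test_identity_decoder_reduces_to_attention(self, rng):
        mha = MultiHeadAttention(4, 2, rng=rng)
        att = ATT(None, mha)
        x = rng.normal(size=(2, 4, 6)).astype(np.float32)
        with no_grad():
            a = att(Tensor(x)).data
            b = mha(Tensor(x.transpose(0, 2, 1))).data.transpose(0, 2, 1)
        np.testing.assert_array_equal(a, b)

    def test_permutation_equivariance_without_decoder(self, rng):
        mha = MultiHeadAttention(4, 2, rng=rng)
        att = ATT(None, mha)
        x = rng.normal(size=(1, 4, 6)).astype(np.float64)
        perm = np.random.default_rng(1).permutation(6)
        with no_grad():
            base = att(Tensor(x)).data
            permuted = att(Tensor(x[:, :, perm])).data
        np.testing.assert_allclose(permuted, base[:, :, perm], atol=1e-10)

    def test_batch_independence(self, rng):
        cfg = TemporalDecoderConfig(n_filters=4, dropout_p=0.0)
        att = ATT(TemporalDecoder(cfg, rng=rng), MultiHeadAttention(4, 2, rng=rng))
        att.eval()
        x1 = rng.normal(size=(1, 4, 10)).astype(np.float32)
        x2 = np.concatenate([x1, x1])
        with no_grad():
            out = att(Tensor(x2)).data
        np.testing.assert_array_equal(out[0], out[1])


class TestDilatedConvProperties:
    """Property-based checks of the reference convolution."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        x=st.lists(st.floats(-10, 10), min_size=1, max_size=30),
        f=st.lists(st.floats(-5, 5), min_size=1, max_size=5),
        d=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity_and_length(self, x, f, d):
        x = np.asarray(x)
        f = np.asarray(f)
        out = dilated_causal_conv(x, f, d)
        assert out.shape == x.shape
        np.testing.assert_allclose(
            dilated_causal_conv(2.0 * x, f, d), 2.0 * out, atol=1e-9
        )

    @given(
        x=st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        f=st.lists(st.floats(-5, 5), min_size=1, max_size=5),
        d=st.integers(1, 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_causality_property(self, x, f, d):
        x = np.asarray(x)
        f = np.asarray(f)
        t0 = len(x) // 2
        x2 = x.copy()
        x2[t0:] += 3.0
        a = dilated_causal_conv(x, f, d)
        b = dilated_causal_conv(x2, f, d)
        np.testing.assert_allclose(a[:t0], b[:t0], atol=1e-9)
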