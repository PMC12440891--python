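"""Building-block checks against hand computation and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscseg import nn
from dscseg.blocks import (
    CBAM,
    BlockSpec,
    ChannelAttention,
    DSDConv,
    InvertedResidual,
    SpatialAttention,
    StripPooling,
    dsd_conv_param_count,
    standard_conv_param_count,
)
from dscseg.nn import Tensor, no_grad

from conftest import set_identity_bn


def _dense_oracle(x, dw, pw, dilation):
    """Brute-force reference: per-channel dilated conv then channel mixing."""
    n, c, h, w = x.shape
    cout = pw.shape[0]
    k = dw.shape[2]
    p = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    depth = np.zeros_like(x)
    for ch in range(c):
        for y in range(h):
            for z in range(w):
                acc = 0.0
                for u in range(k):
                    for v in range(k):
                        acc += dw[ch, 0, u, v] * xp[0, ch, y + u * dilation, z + v * dilation]
                depth[0, ch, y, z] = acc
    out = np.zeros((n, cout, h, w), dtype=np.float64)
    for o in range(cout):
        for ch in range(c):
            out[0, o] += pw[o, ch, 0, 0] * depth[0, ch]
    return out


class TestDSDConv:
    def test_matches_dense_convolution_oracle(self, rng):
        block = DSDConv(3, 4, 3, dilation=2, norm=False, activation=None,
                        rng=rng)
        x = rng.normal(size=(1, 3, 5, 5)).astype(np.float32)
        with no_grad():
            got = block(Tensor(x)).data
        want = _dense_oracle(x, block.depthwise.weight.data,
                             block.pointwise.weight.data, dilation=2)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_zero_input_maps_to_zero(self, rng):
        block = DSDConv(4, 6, 3, norm=False, activation=None, rng=rng)
        with no_grad():
            out = block(Tensor(np.zeros((1, 4, 8, 8), np.float32)))
        assert np.all(out.data == 0)

    def test_parameter_arithmetic_vs_standard_conv(self):
        assert dsd_conv_param_count(64, 64, 3) == 4672
        assert standard_conv_param_count(64, 64, 3) == 36864
        block = DSDConv(64, 64, 3, norm=False, activation=None)
        assert block.num_parameters() == 4672
        # factorized form is smaller whenever more than one output channel
        for cout in (2, 8, 256):
            assert dsd_conv_param_count(64, cout) < standard_conv_param_count(64, cout)

    def test_stride_halves_output(self, rng):
        block = DSDConv(4, 8, 3, stride=2, rng=rng)
        with no_grad():
            out = block.eval()(Tensor(rng.normal(size=(1, 4, 8, 8))))
        assert out.shape == (1, 8, 4, 4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            DSDConv(4, 4, 4)


class TestInvertedResidual:
    def test_zeroed_branch_is_identity(self, rng):
        block = InvertedResidual(8, 8, stride=1, expansion=6, rng=rng).eval()
        for p in block.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(1, 8, 6, 6)).astype(np.float32)
        with no_grad():
            out = block(Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_stride2_shape_and_no_residual(self, rng):
        block = InvertedResidual(16, 24, stride=2, expansion=6, rng=rng).eval()
        assert not block.use_residual
        with no_grad():
            out = block(Tensor(rng.normal(size=(1, 16, 8, 8))))
        assert out.shape == (1, 24, 4, 4)

    def test_matches_hand_composed_stages(self, rng):
        """expand -> depthwise -> project composed independently in NumPy."""
        block = InvertedResidual(24, 24, stride=1, expansion=6, rng=rng).eval()
        # randomize BN inference states so the test exercises them
        for _, m in block.named_modules():
            if isinstance(m, nn.BatchNorm2d):
                m._buffers["running_mean"][...] = rng.normal(size=m.num_features) * 0.1
                m._buffers["running_var"][...] = rng.uniform(0.5, 1.5, m.num_features)
                m.weight.data[...] = rng.uniform(0.5, 1.5, m.num_features)
                m.bias.data[...] = rng.normal(size=m.num_features) * 0.1
        x = rng.normal(size=(1, 24, 5, 5)).astype(np.float32)

        def bn(m, v):
            inv = 1.0 / np.sqrt(m._buffers["running_var"] + m.eps)
            return (v - m._buffers["running_mean"][None, :, None, None]) * \
                inv[None, :, None, None] * m.weight.data[None, :, None, None] + \
                m.bias.data[None, :, None, None]

        def conv_pw(w, v):  # 1x1 conv
            return np.einsum("oc,nchw->nohw", w[:, :, 0, 0], v)

        def conv_dw(w, v):  # 3x3 depthwise, padding 1
            vp = np.pad(v, ((0, 0), (0, 0), (1, 1), (1, 1)))
            out = np.zeros_like(v)
            for u in range(3):
                for t in range(3):
                    out += w[None, :, 0, u, t, None, None] * vp[:, :, u:u + 5, t:t + 5]
            return out

        e = np.clip(bn(block.expand.bn, conv_pw(block.expand.conv.weight.data, x)), 0, 6)
        d = np.clip(bn(block.depthwise.bn, conv_dw(block.depthwise.conv.weight.data, e)), 0, 6)
        want = bn(block.project.bn, conv_pw(block.project.conv.weight.data, d)) + x
        with no_grad():
            got = block(Tensor(x)).data
        np.testing.assert_allclose(got, want, atol=1e-4)


class TestStripPooling:
    @staticmethod
    def _identity_strip(channels, rng):
        sp = StripPooling(channels, rng=rng).eval()
        for conv_bn in (sp.conv_h, sp.conv_v, sp.fuse):
            conv_bn.conv.weight.data[...] = 0.0
            w = conv_bn.conv.weight.data
            center = (w.shape[2] // 2, w.shape[3] // 2)
            w[:, 0, center[0], center[1]] = 1.0
            set_identity_bn(conv_bn.bn)
        return sp

    def test_hand_worked_two_by_two(self, rng):
        sp = self._identity_strip(1, rng)
        x = np.array([[1.0, 2.0], [3.0, 4.0]], np.float32)[None, None]
        with no_grad():
            z = sp(Tensor(x)).data[0, 0]
        fused = np.array([[3.5, 4.5], [5.5, 6.5]])  # y_h=[1.5,3.5], y_v=[2,3]
        want = x[0, 0] / (1.0 + np.exp(-fused))
        np.testing.assert_allclose(z, want, atol=1e-6)

    def test_constant_input_gate(self, rng):
        c = 0.7
        sp = self._identity_strip(2, rng)
        x = np.full((1, 2, 4, 6), c, np.float32)
        with no_grad():
            z = sp(Tensor(x)).data
        np.testing.assert_allclose(z, c / (1.0 + np.exp(-2 * c)), atol=1e-6)

    def test_transpose_symmetry(self, rng):
        """Transposing input and swapping the H/W paths transposes the output."""
        sp = StripPooling(3, rng=rng).eval()
        x = rng.normal(size=(1, 3, 4, 7)).astype(np.float32)
        with no_grad():
            z = sp(Tensor(x)).data
            # swap paths: conv_h <-> conv_v with transposed kernels
            sp.conv_h.conv.weight.data, sp.conv_v.conv.weight.data = (
                sp.conv_v.conv.weight.data.transpose(0, 1, 3, 2),
                sp.conv_h.conv.weight.data.transpose(0, 1, 3, 2),
            )
            zt = sp(Tensor(x.transpose(0, 1, 3, 2))).data
        np.testing.assert_allclose(zt, z.transpose(0, 1, 3, 2), atol=1e-5)

    def test_preserves_shape(self, rng):
        sp = StripPooling(5, rng=rng).eval()
        x = rng.normal(size=(2, 5, 6, 9))
        with no_grad():
            assert sp(Tensor(x)).shape == x.shape


class TestAttention:
    def test_channel_attention_zero_input_gives_half(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=rng)
        with no_grad():
            m = ca(Tensor(np.zeros((1, 4, 3, 3), np.float32)))
        np.testing.assert_allclose(m.data, 0.5)
        assert m.shape == (1, 4, 1, 1)

    def test_channel_attention_constant_input(self, rng):
        ca = ChannelAttention(2, reduction=16, rng=rng)
        # identity perceptron: fc1 sums both channels? keep it literal:
        ca.fc1.weight.data[...] = np.array([[1.0], [0.0]], np.float32)
        ca.fc2.weight.data[...] = np.array([[1.0, 0.0]], np.float32)
        c = 0.9
        with no_grad():
            m = ca(Tensor(np.full((1, 2, 2, 2), c, np.float32))).data
        # max pool == avg pool == c; mlp keeps channel 0: sigma(2c) there
        np.testing.assert_allclose(m[0, 0, 0, 0], 1 / (1 + np.exp(-2 * c)), rtol=1e-5)
        np.testing.assert_allclose(m[0, 1, 0, 0], 0.5, rtol=1e-5)

    def test_channel_attention_hand_matrix_arithmetic(self, rng):
        ca = ChannelAttention(2, reduction=2, rng=rng)
        w1 = np.array([[0.3], [-0.2]], np.float32)
        w2 = np.array([[0.5, -0.4]], np.float32)
        ca.fc1.weight.data[...] = w1
        ca.fc2.weight.data[...] = w2
        x = rng.normal(size=(1, 2, 2, 2)).astype(np.float32)
        with no_grad():
            got = ca(Tensor(x)).data[0, :, 0, 0]
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        mlp = lambda v: np.maximum(v @ w1, 0) @ w2
        want = 1 / (1 + np.exp(-(mlp(avg) + mlp(mx))))
        np.testing.assert_allclose(got, want[0], atol=1e-5)

    def test_channel_attention_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttention(48, reduction=32)

    def test_spatial_attention_window_sum_oracle(self, rng):
        sa = SpatialAttention(kernel=7, rng=rng)
        sa.conv.weight.data[...] = 1.0
        sa.conv.bias.data[...] = 0.0
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        with no_grad():
            got = sa(Tensor(x)).data[0, 0]
        stacked = np.stack([x.mean(axis=1)[0], x.max(axis=1)[0]])
        sp = np.pad(stacked, ((0, 0), (3, 3), (3, 3)))
        want = np.zeros((4, 4))
        for y in range(4):
            for z in range(4):
                want[y, z] = sp[:, y:y + 7, z:z + 7].sum()
        np.testing.assert_allclose(got, 1 / (1 + np.exp(-want)), atol=1e-5)

    def test_spatial_attention_zero_input_gives_half(self, rng):
        sa = SpatialAttention(rng=rng)
        sa.conv.bias.data[...] = 0.0
        with no_grad():
            m = sa(Tensor(np.zeros((2, 5, 6, 7), np.float32)))
        np.testing.assert_allclose(m.data, 0.5)
        assert m.shape == (2, 1, 6, 7)

    def test_cbam_equals_manual_composition(self, rng):
        cbam = CBAM(4, reduction=2, rng=rng)
        x = rng.normal(size=(2, 4, 5, 5)).astype(np.float32)
        with no_grad():
            got = cbam(Tensor(x)).data
            g = x * cbam.channel(Tensor(x)).data
            want = g * cbam.spatial(Tensor(g)).data
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_cbam_zero_in_zero_out_and_bounded(self, rng):
        cbam = CBAM(4, reduction=2, rng=rng)
        with no_grad():
            out = cbam(Tensor(np.zeros((1, 4, 3, 3), np.float32)))
            assert np.all(out.data == 0)
            x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
            out = cbam(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x))


@settings(deadline=None, max_examples=20)
@given(
    c=st.integers(1, 8),
    h=st.integers(1, 9),
    w=st.integers(1, 9),
    data_seed=st.integers(0, 2**31 - 1),
)
def test_gates_strictly_in_unit_interval_and_shapes_preserved(c, h, w, data_seed):
    """Attention and strip-pooling gates stay in (0,1); shapes are preserved."""
    rng = np.random.default_rng(data_seed)
    x = Tensor(rng.normal(scale=5.0, size=(1, c, h, w)))
    ca = ChannelAttention(c, reduction=1, rng=rng)
    sa = SpatialAttention(rng=rng)
    sp = StripPooling(c, rng=rng).eval()
    cbam = CBAM(c, reduction=1, rng=rng).eval()
    with no_grad():
        mc = ca(x).data
        ms = sa(x).data
        assert np.all((mc > 0) & (mc < 1))
        assert np.all((ms > 0) & (ms < 1))
        assert ms.shape == (1, 1, h, w)
        assert sp(x).shape == x.shape
        assert cbam(x).shape == x.shape


def test_block_spec_validation():
    with pytest.raises(ValueError):
        BlockSpec(4, 4, kernel=2)
    with pytest.raises(ValueError):
        BlockSpec(4, 4, stride=3)
    with pytest.raises(ValueError):
        BlockSpec(4, 4, dilation=0)
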