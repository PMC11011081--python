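"""Unit and property tests for the backbone layers.

The temporal shift is checked against an index-arithmetic oracle and for
exact value conservation; attention against softmax normalization and a
brute-force uniform-attention argument; channel attention against a
closed-form hand evaluation; residual blocks against shape arithmetic and
the identity-at-initialization contract.
"""

import numpy as np
import pytest

from pbatn.autograd import Tensor, no_grad
from pbatn.backbone import (
    Backbone,
    BackboneConfig,
    Bottleneck,
    ChannelAttention,
    LocalSelfAttention,
    avg_pool2d,
    temporal_shift,
)


class TestTemporalShift:
    def test_two_frame_index_arithmetic(self):
        # x[t, c] = 10(t+1) + c on a T=2, C=8, 1×1 stack
        x = np.zeros((2, 8, 1, 1), dtype=np.float32)
        for t in range(2):
            for c in range(8):
                x[t, c] = 10 * (t + 1) + c
        out = temporal_shift(x, 0.125)
        assert out[0, 0, 0, 0] == 0.0  # forward-shifted channel, no predecessor
        assert out[1, 0, 0, 0] == 10.0  # frame 1 inherits frame 0
        assert out[0, 1, 0, 0] == 21.0  # backward-shifted channel from frame 1
        assert out[1, 1, 0, 0] == 0.0  # no successor
        np.testing.assert_array_equal(out[:, 2:], x[:, 2:])

    def test_one_channel_per_direction_at_eighth(self):
        x = np.random.default_rng(0).normal(size=(4, 8, 2, 2)).astype(np.float32)
        out = temporal_shift(x, 0.125)
        changed = [c for c in range(8) if not np.array_equal(out[:, c], x[:, c])]
        assert changed == [0, 1]

    def test_single_frame_zeroes_shifted_channels(self):
        x = np.random.default_rng(1).normal(size=(1, 8, 3, 3)).astype(np.float32)
        out = temporal_shift(x, 0.125)
        assert np.all(out[:, :2] == 0)
        np.testing.assert_array_equal(out[:, 2:], x[:, 2:])

    def test_value_conservation_multiset(self):
        """Non-boundary entries of shifted channels are moved, never altered."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 16, 4, 4)).astype(np.float32)
        out = temporal_shift(x, 0.125)
        n = 2  # floor(16/8)
        np.testing.assert_array_equal(out[1:, :n], x[:-1, :n])  # exact, no arithmetic
        np.testing.assert_array_equal(out[:-1, n : 2 * n], x[1:, n : 2 * n])

    def test_inverse_shift_recovers_interior_frames(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(6, 8, 2, 2)).astype(np.float32)
        y = temporal_shift(x, 0.125)
        # invert: swap shift directions by swapping the two shifted blocks
        y_swapped = y.copy()
        y_swapped[:, 0], y_swapped[:, 1] = y[:, 1], y[:, 0]
        z = temporal_shift(y_swapped, 0.125)
        z[:, 0], z[:, 1] = z[:, 1].copy(), z[:, 0].copy()
        np.testing.assert_array_equal(z[1:-1], x[1:-1])

    def test_zero_fraction_is_identity(self):
        x = np.random.default_rng(4).normal(size=(3, 8, 2, 2)).astype(np.float32)
        np.testing.assert_array_equal(temporal_shift(x, 0.0), x)

    def test_too_small_channel_count_errors(self):
        with pytest.raises(ValueError, match="moves no channels"):
            temporal_shift(np.zeros((2, 4, 1, 1), dtype=np.float32), 0.125)


class TestLocalSelfAttention:
    def test_weights_sum_to_one_everywhere(self):
        rng = np.random.default_rng(5)
        attn = LocalSelfAttention(8, heads=2, rng=rng)
        attn.rel_pos.data = rng.normal(size=attn.rel_pos.shape).astype(np.float32)
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        w = attn.attention_weights(x)
        np.testing.assert_allclose(w.sum(axis=2), 1.0, atol=1e-6)

    def test_constant_input_stays_constant_in_interior(self):
        """Uniform values ⇒ the weighted value sum is the same everywhere the
        window sees no zero padding, regardless of the attention weights."""
        rng = np.random.default_rng(6)
        attn = LocalSelfAttention(8, heads=2, rng=rng)
        x = np.full((1, 8, 5, 5), 1.7, dtype=np.float32)
        with no_grad():
            out = attn(Tensor(x)).data
        interior = out[:, :, 1:-1, 1:-1]
        np.testing.assert_allclose(
            interior,
            np.broadcast_to(interior[:, :, :1, :1], interior.shape),
            rtol=1e-5,
            atol=1e-5,
        )

    def test_matches_bruteforce_single_head(self):
        """Dot-product/softmax/weighted-sum recomputed position by position."""
        rng = np.random.default_rng(7)
        attn = LocalSelfAttention(4, heads=1, rng=rng)
        attn.rel_pos.data = rng.normal(size=(1, 9)).astype(np.float32) * 0.3
        x = rng.normal(size=(1, 4, 5, 5)).astype(np.float32)
        with no_grad():
            out = attn(Tensor(x)).data
            q = attn.query(Tensor(x)).data[0]
            k = attn.key(Tensor(x)).data[0]
            v = attn.value(Tensor(x)).data[0]
        kp = np.pad(k, ((0, 0), (1, 1), (1, 1)))
        vp = np.pad(v, ((0, 0), (1, 1), (1, 1)))
        for i in range(5):
            for j in range(5):
                logits, vals = [], []
                widx = 0
                for di in range(3):
                    for dj in range(3):
                        kv = kp[:, i + di, j + dj]
                        logits.append(
                            q[:, i, j] @ kv / np.sqrt(4.0)
                            + attn.rel_pos.data[0, widx]
                        )
                        vals.append(vp[:, i + di, j + dj])
                        widx += 1
                e = np.exp(np.array(logits) - max(logits))
                w = e / e.sum()
                expected = (np.array(vals) * w[:, None]).sum(axis=0)
                np.testing.assert_allclose(out[0, :, i, j], expected, atol=1e-4)

    def test_stride_two_halves_resolution(self):
        attn = LocalSelfAttention(8, heads=2, stride=2, rng=np.random.default_rng(8))
        x = Tensor(np.random.default_rng(9).normal(size=(1, 8, 56, 56)))
        with no_grad():
            assert attn(x).shape == (1, 8, 28, 28)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            LocalSelfAttention(8, window=4)


class TestChannelAttention:
    def test_zero_input_zero_output(self):
        ca = ChannelAttention(8, 4, rng=np.random.default_rng(10))
        x = Tensor(np.zeros((1, 8, 3, 3), dtype=np.float32))
        with no_grad():
            assert np.all(ca(x).data == 0)

    def test_strict_attenuation(self):
        rng = np.random.default_rng(11)
        ca = ChannelAttention(8, 4, rng=rng)
        x = rng.normal(size=(2, 8, 4, 4)).astype(np.float32)
        with no_grad():
            out = ca(Tensor(x)).data
        nz = x != 0
        assert np.all(np.abs(out[nz]) < np.abs(x[nz]))

    def test_hand_set_weights_closed_form(self):
        ca = ChannelAttention(4, 2, rng=np.random.default_rng(12))
        ca.squeeze.weight.data = np.array(
            [[1, 0], [0, 1], [1, 0], [0, 1]], dtype=np.float32
        )
        ca.squeeze.bias.data = np.zeros(2, dtype=np.float32)
        ca.excite.weight.data = np.array(
            [[1, 0, 0, 0], [0, 1, 0, 0]], dtype=np.float32
        )
        ca.excite.bias.data = np.zeros(4, dtype=np.float32)
        x = np.array([1.0, 2.0, 3.0, 4.0], dtype=np.float32).reshape(1, 4, 1, 1)
        # squeeze: [1+3, 2+4] = [4, 6]; relu passes; excite -> [4, 6, 0, 0]
        expected_scale = 1 / (1 + np.exp(-np.array([4.0, 6.0, 0.0, 0.0])))
        with no_grad():
            out = ca(Tensor(x)).data[0, :, 0, 0]
        np.testing.assert_allclose(
            out, x[0, :, 0, 0] * expected_scale, rtol=1e-5
        )

    def test_indivisible_reduction_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            ChannelAttention(6, 4)

    def test_homogeneous_with_frozen_scale(self):
        """With the squeeze path frozen (scale fixed), the gate is linear."""
        rng = np.random.default_rng(13)
        ca = ChannelAttention(8, 4, rng=rng)
        x = rng.normal(size=(1, 8, 3, 3)).astype(np.float32)
        with no_grad():
            s = ca.scale(Tensor(x)).data
        out1 = x * s.reshape(1, 8, 1, 1)
        out3 = (3.0 * x) * s.reshape(1, 8, 1, 1)
        np.testing.assert_allclose(out3, 3.0 * out1, rtol=1e-6)


class TestBottleneck:
    CFG = BackboneConfig.tiny()

    def test_identity_at_initialization(self):
        """Zero-initialized final scale makes each block ReLU(identity)."""
        rng = np.random.default_rng(14)
        blk = Bottleneck("identity", 32, 8, 1, self.CFG, rng)
        x = rng.normal(size=(8, 32, 4, 4)).astype(np.float32)
        with no_grad():
            out = blk(Tensor(x)).data
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-6)

    def test_convolution_block_strides_and_projects(self):
        rng = np.random.default_rng(15)
        blk = Bottleneck("convolution", 32, 16, 2, self.CFG, rng)
        x = Tensor(np.random.default_rng(16).normal(size=(8, 32, 8, 8)))
        with no_grad():
            out = blk(x)
        assert out.shape == (8, 64, 4, 4)

    def test_identity_block_cannot_stride(self):
        with pytest.raises(ValueError, match="identity block"):
            Bottleneck("identity", 32, 8, 2, self.CFG, np.random.default_rng(0))

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(17)
        blk = Bottleneck("identity", 32, 8, 1, self.CFG, rng)
        with pytest.raises(ValueError, match="channels"):
            with no_grad():
                blk(Tensor(np.zeros((8, 16, 4, 4), dtype=np.float32)))


class TestBackbone:
    def test_tiny_shape_chain_and_feature_dim(self):
        bb = Backbone(BackboneConfig.tiny(), seed=0)
        x = Tensor(np.random.default_rng(18).normal(size=(8, 3, 64, 64)))
        with no_grad():
            maps, shapes = bb.forward_maps(x)
        assert shapes["conv1"] == (16, 32, 32)
        assert shapes["maxpool"] == (16, 16, 16)
        assert shapes["conv2_x"] == (32, 16, 16)
        assert shapes["conv3_x"] == (64, 8, 8)
        assert shapes["conv4_x"] == (128, 4, 4)
        assert shapes["conv5_x"] == (256, 2, 2)
        assert bb.feature_dim == 256

    def test_eval_determinism(self):
        bb = Backbone(BackboneConfig.tiny(), seed=1)
        x = np.random.default_rng(19).normal(size=(8, 3, 32, 32)).astype(np.float32)
        from pbatn.backbone import backbone_forward

        f1 = backbone_forward(bb, x)
        f2 = backbone_forward(bb, x)
        np.testing.assert_array_equal(f1, f2)

    def test_parameter_count_resolution_invariant(self):
        """Relative (not absolute) position terms: one count for all sizes."""
        bb = Backbone(BackboneConfig.tiny(), seed=2)
        n0 = bb.num_parameters()
        from pbatn.backbone import backbone_forward

        backbone_forward(bb, np.zeros((8, 3, 32, 32), dtype=np.float32))
        backbone_forward(bb, np.zeros((8, 3, 64, 64), dtype=np.float32))
        assert bb.num_parameters() == n0

    def test_gn_divisibility_enforced(self):
        with pytest.raises(ValueError, match="not divisible"):
            BackboneConfig(stage_widths=(48, 96, 192, 384))

    def test_wrong_channel_count_rejected(self):
        bb = Backbone(BackboneConfig.tiny(), seed=3)
        with pytest.raises(ValueError, match="3 input channels"):
            with no_grad():
                bb(Tensor(np.zeros((8, 4, 64, 64), dtype=np.float32)))


def test_avg_pool_requires_divisible_dims():
    with pytest.raises(ValueError, match="not divisible"):
        avg_pool2d(Tensor(np.zeros((1, 2, 5, 5), dtype=np.float32)), 2)
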