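"""Learnable blocks: reduction to the plain EdgeConv reference, gate and
mask ranges, and the algebraic identities of the attention modules."""

import numpy as np
import pytest

from pointattn import autodiff as ad
from pointattn.autodiff import Tensor
from pointattn.geometry import geometric_descriptor, knn_group
from pointattn.layers import (AttentionMask, ChannelGate, EdgeConvBlock,
                              GlobalAttentionHead, GlobalFeatureBlock,
                              SpatialAttentionEdgeConv, apply_mask,
                              cw_edgeconv, cw_edgeconv_pp,
                              global_attention_mask, global_feature,
                              hard_attention_mask, se_gate,
                              spatial_attention_edgeconv)

RNG = np.random.default_rng(21)


def random_block(cin, cout, k, gated=True, seed=0):
    """An EdgeConv block with randomized BN statistics and affine map so
    the inference-path comparison is non-trivial."""
    rng = np.random.default_rng(seed)
    block = EdgeConvBlock(cin, cout, k, rng, gated=gated)
    block.bn.gamma.data = rng.uniform(0.5, 1.5, size=cout)
    block.bn.beta.data = rng.normal(size=cout)
    object.__setattr__(block.bn, "running_mean", rng.normal(size=cout) * 0.1)
    object.__setattr__(block.bn, "running_var", rng.uniform(0.5, 2.0, size=cout))
    return block


def edgeconv_reference(pts, block):
    """Independent plain-EdgeConv oracle: kNN groups, shared MLP on the
    (x_j - x_i, x_i) pairs, batch norm (inference), activation, max."""
    nbr = knn_group(pts, block.k)
    xj = pts[nbr.indices]
    xi = np.broadcast_to(pts[:, None, :], xj.shape)
    edge = np.concatenate([xj - xi, xi], axis=2)
    W = np.vstack([block.mlp_diff.weight.data, block.mlp_center.weight.data])
    h = edge @ W + block.mlp_center.bias.data
    bn = block.bn
    h = ((h - bn.running_mean) / np.sqrt(bn.running_var + bn.eps)
         * bn.gamma.data + bn.beta.data)
    h = np.where(h > 0, h, 0.2 * h)
    return h.max(axis=1)


class TestChannelGate:
    def test_zeroed_excitation_halves_input(self):
        gate = ChannelGate(6, np.random.default_rng(0))
        gate.fc2.weight.data[:] = 0.0
        gate.fc2.bias.data[:] = 0.0
        x = RNG.normal(size=(8, 4, 6))
        np.testing.assert_allclose(se_gate(x, gate), x / 2.0, rtol=1e-12)

    def test_ratio_constant_across_positions_and_in_unit_interval(self):
        gate = ChannelGate(5, np.random.default_rng(1))
        x = RNG.normal(size=(7, 3, 5)) + 2.0
        out = se_gate(x, gate)
        ratio = out / x
        np.testing.assert_allclose(ratio - ratio[0, 0], 0.0, atol=1e-9)
        assert ((ratio > 0) & (ratio < 1)).all()

    def test_zero_input_maps_to_zero(self):
        gate = ChannelGate(4, np.random.default_rng(2))
        out = se_gate(np.zeros((5, 2, 4)), gate)
        np.testing.assert_allclose(out, 0.0)

    def test_channel_mismatch_rejected(self):
        gate = ChannelGate(4, np.random.default_rng(3))
        with pytest.raises(ValueError):
            se_gate(np.zeros((5, 2, 3)), gate)


class TestCwEdgeConv:
    def test_identity_gate_reduces_to_edgeconv_reference(self):
        rng = np.random.default_rng(31)
        for trial in range(50):
            n = int(rng.integers(6, 20))
            k = int(rng.integers(1, n + 1))
            cin = int(rng.integers(2, 5))
            cout = int(rng.integers(2, 7))
            block = random_block(cin, cout, k, seed=trial)
            block.gate.identity = True
            pts = rng.normal(size=(n, cin))
            ours = cw_edgeconv(pts, block)
            ref = edgeconv_reference(pts, block)
            np.testing.assert_allclose(ours, ref, rtol=1e-5, atol=1e-8)

    def test_k1_is_gated_center_feature(self):
        block = random_block(3, 4, 1, seed=5)
        pts = RNG.normal(size=(6, 3))
        out = cw_edgeconv(pts, block)
        assert out.shape == (6, 4)
        block.gate.identity = True
        np.testing.assert_allclose(cw_edgeconv(pts, block),
                                   edgeconv_reference(pts, block))

    def test_permutation_equivariance(self):
        block = random_block(3, 5, 4, seed=6)
        pts = RNG.normal(size=(15, 3))
        out = cw_edgeconv(pts, block)
        perm = np.random.default_rng(1).permutation(15)
        out_p = cw_edgeconv(pts[perm], block)
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-6, atol=1e-9)


class TestCwEdgeConvPP:
    def test_descriptor_and_shared_grouping(self):
        block = random_block(3, 4, 5, seed=7)
        pts = RNG.normal(size=(12, 3))
        out, desc = cw_edgeconv_pp(pts, block)
        assert desc.channels == 10
        np.testing.assert_allclose(out, cw_edgeconv(pts, block))
        nbr = knn_group(pts, 5)
        np.testing.assert_allclose(
            desc.values, geometric_descriptor(pts, nbr).values)


class TestGlobalFeature:
    def test_concat_width_and_zeroed_excitation(self):
        rng = np.random.default_rng(8)
        gf = GlobalFeatureBlock(16, 24, rng)
        outs = [RNG.normal(size=(10, c)) for c in (4, 4, 8)]
        g = global_feature(outs, gf)
        assert g.shape == (10, 24)
        gf.gate.fc2.weight.data[:] = 0.0
        gf.gate.fc2.bias.data[:] = 0.0
        g_half = global_feature(outs, gf)
        # zeroed excitation leaves a gate of exactly 1/2
        full = 2.0 * g_half
        gf.gate.identity = True
        np.testing.assert_allclose(global_feature(outs, gf), full, rtol=1e-6)

    def test_mismatched_point_counts_rejected(self):
        gf = GlobalFeatureBlock(8, 8, np.random.default_rng(9))
        with pytest.raises(ValueError):
            global_feature([np.zeros((5, 4)), np.zeros((6, 4))], gf)


class TestAttentionMasks:
    def setup_method(self):
        self.head = GlobalAttentionHead(np.random.default_rng(10), hidden=8)
        pts = RNG.normal(size=(20, 3))
        self.desc = geometric_descriptor(pts, knn_group(pts, 4))

    def test_soft_mask_strictly_inside_unit_interval(self):
        mask = global_attention_mask(self.desc, self.head)
        assert mask.mode == "soft"
        assert ((mask.weights > 0) & (mask.weights < 1)).all()

    def test_zeroed_final_stage_gives_half(self):
        self.head.fc2.weight.data[:] = 0.0
        self.head.fc2.bias.data[:] = 0.0
        mask = global_attention_mask(self.desc, self.head)
        np.testing.assert_allclose(mask.weights, 0.5)

    def test_group_permutation_leaves_weight_unchanged(self):
        mask = global_attention_mask(self.desc, self.head)
        vals = self.desc.values.copy()
        rng = np.random.default_rng(3)
        for i in range(len(vals)):
            vals[i] = vals[i][rng.permutation(vals.shape[1])]
        shuffled = type(self.desc)(vals)
        mask2 = global_attention_mask(shuffled, self.head)
        np.testing.assert_allclose(mask2.weights, mask.weights, rtol=1e-6)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            global_attention_mask(
                type(self.desc)(self.desc.values[:, :, :9]), self.head)

    def test_hard_mask_binary_with_inclusive_boundary(self):
        mask = hard_attention_mask(self.desc, self.head)
        assert mask.mode == "hard"
        assert np.isin(mask.weights, (0.0, 1.0)).all()
        # zeroed final stage: mean response exactly 0.5 -> all ones
        self.head.fc2.weight.data[:] = 0.0
        self.head.fc2.bias.data[:] = 0.0
        ones = hard_attention_mask(self.desc, self.head)
        np.testing.assert_allclose(ones.weights, 1.0)

    def test_hard_mask_monotone_in_bias(self):
        before = hard_attention_mask(self.desc, self.head).weights
        self.head.fc2.bias.data[:] += 2.0
        after = hard_attention_mask(self.desc, self.head).weights
        assert (after >= before).all()


class TestSpatialAttention:
    def test_saturated_mask_equals_plain_edgeconv(self):
        rng = np.random.default_rng(12)
        sa = SpatialAttentionEdgeConv(3, 6, 4, rng)
        edge = sa.edge
        edge.bn.gamma.data = rng.uniform(0.5, 1.5, size=6)
        pts = RNG.normal(size=(14, 3))
        # saturate the sigmoid with a huge positive bias
        sa.mask_bn.beta.data[:] = 50.0
        out = spatial_attention_edgeconv(pts, pts, sa)
        ref = edgeconv_reference(pts, edge)
        np.testing.assert_allclose(out, ref, rtol=1e-5, atol=1e-8)

    def test_output_is_contraction_of_edgeconv(self):
        sa = SpatialAttentionEdgeConv(3, 5, 4, np.random.default_rng(13))
        pts = RNG.normal(size=(16, 3))
        out = spatial_attention_edgeconv(pts, pts, sa)
        ref = edgeconv_reference(pts, sa.edge)
        assert (np.abs(out) <= np.abs(ref) + 1e-12).all()

    def test_mask_branch_consumes_nine_channels(self):
        sa = SpatialAttentionEdgeConv(3, 5, 4, np.random.default_rng(14))
        assert sa.mask_mlp.weight.shape[0] == 9


class TestApplyMask:
    def test_identities(self):
        g = np.abs(RNG.normal(size=(6, 8)))
        ones = AttentionMask(np.full(6, 1.0 - 1e-9), mode="soft")
        np.testing.assert_allclose(apply_mask(g, ones), g, rtol=1e-6)
        hard = AttentionMask(np.array([1, 0, 1, 1, 0, 1.0]), mode="hard")
        out = apply_mask(g, hard)
        assert (out[1] == 0).all() and (out[4] == 0).all()
        g2 = g.copy()
        g2[0, 0] = -3.0
        assert apply_mask(g2, hard)[0, 0] == 0.0

    def test_mask_validation(self):
        with pytest.raises(ValueError):
            AttentionMask(np.array([0.0, 0.5]), mode="soft")
        with pytest.raises(ValueError):
            AttentionMask(np.array([0.5]), mode="hard")
        with pytest.raises(ValueError):
            apply_mask(np.zeros((3, 2)),
                       AttentionMask(np.array([0.5, 0.5]), mode="soft"))


def test_se_scalars_strictly_inside_unit_interval():
    gate = ChannelGate(7, np.random.default_rng(15))
    x = Tensor(RNG.normal(size=(2, 9, 7)))
    s = gate.scalars(x).data
    assert ((s > 0) & (s < 1)).all()
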