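"""Architecture contracts: printed feature-map shapes, the output-size
formula, attention identities and the splicing pipeline."""

import numpy as np
import pytest

from safnet.model import (
    ASPP,
    ChannelAttention3D,
    MultiscaleFusion,
    PositionAttention3D,
    ResidualBlock,
    SAFNet,
    SAFNetConfig,
    conv_output_size,
    effective_kernel,
    scene_gate,
)
from safnet.nn import CBR, Conv3d, Tensor, no_grad


def tensor(rng, *shape):
    return Tensor(rng.normal(size=shape).astype(np.float32))


class TestShapeFormulas:
    @pytest.mark.parametrize("i,k,s,p,d,expected", [
        (256, 3, 2, 1, 1, 128),   # stride-2 halving
        (16, 3, 1, 2, 2, 16),     # dilation 2, pad 2 preserves size
        (8, 3, 1, 18, 18, 8),     # ASPP-style rate 18 preserves size
        (32, 3, 2, 2, 2, 16),     # dilated + strided encoder step
        (5, 1, 1, 0, 1, 5),       # pointwise
    ])
    def test_conv_output_size(self, i, k, s, p, d, expected):
        assert conv_output_size(i, k, s, p, d) == expected

    def test_effective_kernel_extent(self):
        assert effective_kernel(3, 6) == 13
        assert effective_kernel(3, 1) == 3

    def test_formula_matches_every_convolution_in_the_network(
            self, desk_model, desk_model_cfg, rng):
        x = tensor(rng, 1, 1, *desk_model_cfg.input_shape)
        desk_model.eval()
        with no_grad():
            desk_model(x)
        convs = [m for m in desk_model.modules() if isinstance(m, Conv3d)]
        assert len(convs) > 30
        for conv in convs:
            in_sp, out_sp = conv.last_io
            assert conv.expected_output_spatial(in_sp) == out_sp


class TestEncoder:
    def test_desk_scale_feature_pyramid(self, desk_model, desk_model_cfg):
        d, h, w = desk_model_cfg.input_shape
        x = Tensor(np.zeros((1, 1, d, h, w), np.float32))
        desk_model.eval()
        with no_grad():
            fl, fm, fh = desk_model.extract_features(x)
        c = desk_model_cfg.base_channels
        assert fl.shape == (1, c, d, h // 4, w // 4)
        assert fm.shape == (1, c, d, h // 8, w // 8)
        assert fh.shape == (1, c, d, h // 16, w // 16)

    def test_depth_axis_never_downsampled(self, desk_model):
        for conv in (m for m in desk_model.modules()
                     if isinstance(m, Conv3d)):
            assert conv.stride[0] == 1
            assert conv.dilation[0] == 1

    def test_same_seed_gives_identical_parameters(self, desk_model_cfg):
        a = SAFNet(desk_model_cfg, seed=3)
        b = SAFNet(desk_model_cfg, seed=3)
        assert a.num_parameters() == b.num_parameters()
        for (na, pa), (nb, pb) in zip(sorted(a.named_parameters()),
                                      sorted(b.named_parameters())):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)


class TestBlocks:
    def test_cbr_reduces_to_bias_with_neutral_norm(self, rng):
        # zero weights, positive bias, eval-mode running stats (0, 1):
        # out = relu((b - 0) / sqrt(1 + eps)) ~ b everywhere
        cbr = CBR(2, 3, 3, padding=1, rng=rng)
        cbr.eval()
        cbr.conv.weight.data[:] = 0
        cbr.conv.bias.data[:] = [0.7, 1.3, 2.0]
        out = cbr(tensor(rng, 1, 2, 3, 4, 5))
        for c, b in enumerate([0.7, 1.3, 2.0]):
            np.testing.assert_allclose(out.data[0, c], b, rtol=1e-4)

    def test_cbr_output_nonnegative(self, rng):
        cbr = CBR(2, 4, 3, padding=1, rng=rng)
        out = cbr(tensor(rng, 2, 2, 4, 6, 5))
        assert out.data.min() >= 0

    def test_residual_block_zero_deep_branch_equals_skip(self, rng):
        block = ResidualBlock(4, 4, stride=(1, 2, 2), rng=rng)
        block.eval()
        block.deep2.conv.weight.data[:] = 0
        block.deep2.conv.bias.data[:] = 0
        x = tensor(rng, 1, 4, 4, 8, 8)
        np.testing.assert_allclose(block(x).data, block.skip(x).data,
                                   atol=1e-6)

    def test_residual_block_printed_midlevel_shape(self, rng):
        # the mid-level step: 128ch 18x64x32 -> 128ch 18x32x16
        block = ResidualBlock(8, 8, stride=(1, 2, 2), rng=rng)
        out = block(tensor(rng, 1, 8, 18, 64, 32))
        assert out.shape == (1, 8, 18, 32, 16)

    def test_residual_block_stride_one_preserves_shape(self, rng):
        block = ResidualBlock(4, 4, stride=(1, 1, 1), rng=rng)
        x = tensor(rng, 1, 4, 3, 8, 8)
        assert block(x).shape == x.shape


class TestASPP:
    def test_spatial_size_preserved(self, rng):
        aspp = ASPP(8, (6, 12, 18), rng=rng)
        x = tensor(rng, 1, 8, 6, 8, 4)
        assert aspp(x).shape == x.shape

    def test_pool_branch_constant_for_constant_input(self, rng):
        aspp = ASPP(8, (6, 12, 18), rng=rng)
        x = Tensor(np.full((1, 8, 4, 4, 4), 2.5, np.float32))
        pooled = aspp.pool_conv(x.mean(axis=(2, 3, 4), keepdims=True)).relu()
        gap = x.data.mean(axis=(2, 3, 4))
        np.testing.assert_allclose(gap, 2.5, atol=1e-6)
        assert pooled.shape == (1, 8, 1, 1, 1)


class TestAttention:
    def test_position_affinity_rows_sum_to_one(self, rng):
        att = PositionAttention3D(8, rng=rng)
        aff = att.affinity(tensor(rng, 2, 8, 3, 4, 2)).data
        assert aff.shape == (2, 24, 24)
        np.testing.assert_allclose(aff.sum(axis=2), 1.0, atol=1e-5)

    def test_position_attention_identity_at_zero_gate(self, rng):
        att = PositionAttention3D(8, rng=rng)
        x = tensor(rng, 1, 8, 3, 4, 2)
        np.testing.assert_array_equal(att(x).data, x.data)

    def test_position_attention_guards_huge_grids(self, rng):
        att = PositionAttention3D(8, rng=rng)
        with pytest.raises(ValueError, match="smaller feature map"):
            att(Tensor(np.zeros((1, 8, 32, 32, 32), np.float32)))

    def test_channel_affinity_rows_sum_to_one(self, rng):
        att = ChannelAttention3D()
        aff = att.affinity(tensor(rng, 2, 6, 3, 4, 2)).data
        assert aff.shape == (2, 6, 6)
        np.testing.assert_allclose(aff.sum(axis=2), 1.0, atol=1e-5)

    def test_channel_attention_identity_at_zero_gate(self, rng):
        att = ChannelAttention3D()
        x = tensor(rng, 1, 6, 3, 4, 2)
        np.testing.assert_array_equal(att(x).data, x.data)

    def test_channel_attention_is_spatially_equivariant(self, rng):
        att = ChannelAttention3D()
        att.gate.data[:] = 0.7
        x = rng.normal(size=(1, 6, 2, 2, 4)).astype(np.float32)
        perm = np.concatenate([x[..., 2:], x[..., :2]], axis=4)
        out = att(Tensor(x)).data
        out_perm = att(Tensor(perm)).data
        np.testing.assert_allclose(
            out_perm, np.concatenate([out[..., 2:], out[..., :2]], axis=4),
            atol=1e-5)


class TestFusionAndSplicing:
    def test_fusion_preserves_shape_and_channel_count(self, rng):
        fusion = MultiscaleFusion(8, rng=rng)
        x = tensor(rng, 1, 8, 4, 8, 8)
        out = fusion(x)
        assert out.shape == x.shape  # 4 branches of C/4 concatenate to C

    def test_fusion_zeroed_later_branches_silence_their_channels(self, rng):
        fusion = MultiscaleFusion(8, rng=rng)
        fusion.eval()
        for i in (1, 2, 3):
            fusion.reduces[i].conv.weight.data[:] = 0
            fusion.reduces[i].conv.bias.data[:] = 0
            fusion.convs[i].conv.weight.data[:] = 0
            fusion.convs[i].conv.bias.data[:] = 0
        out = fusion(tensor(rng, 1, 8, 4, 8, 8))
        assert np.abs(out.data[:, 2:]).max() == 0
        assert np.abs(out.data[:, :2]).max() > 0

    def test_scene_gate_of_constant_channels(self):
        x = Tensor(np.zeros((1, 3, 2, 2, 2), np.float32))
        np.testing.assert_allclose(scene_gate(x).data, 0.5, atol=1e-7)

    def test_scene_gate_strictly_inside_unit_interval(self, rng):
        g = scene_gate(tensor(rng, 2, 4, 3, 3, 3)).data
        assert g.shape == (2, 4, 1, 1, 1)
        assert np.all((g > 0) & (g < 1))


class TestFullForward:
    def test_probabilities_form_a_simplex(self, desk_model, desk_model_cfg,
                                          rng):
        x = rng.normal(size=(1, 1, *desk_model_cfg.input_shape)).astype(
            np.float32)
        probs = desk_model.predict_proba(x)
        assert probs.shape == (1, desk_model_cfg.num_classes,
                               *desk_model_cfg.input_shape)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_identical_batch_entries_give_identical_outputs(
            self, desk_model, desk_model_cfg, rng):
        one = rng.normal(size=(1, 1, *desk_model_cfg.input_shape)).astype(
            np.float32)
        two = np.concatenate([one, one])
        probs = desk_model.predict_proba(two)
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-6)

    def test_argmax_is_a_valid_label_map(self, desk_model, desk_model_cfg,
                                         rng):
        x = rng.normal(size=(1, 1, *desk_model_cfg.input_shape)).astype(
            np.float32)
        labels = desk_model.predict_labels(x)
        assert labels.min() >= 0
        assert labels.max() < desk_model_cfg.num_classes

    def test_forced_unit_gate_makes_splice_a_pure_product(self, rng):
        # with the channel gate forced to 1, F_sh = F_l' * F_m'
        a = Tensor(rng.normal(size=(1, 4, 2, 4, 4)).astype(np.float32))
        b = Tensor(rng.normal(size=(1, 4, 2, 4, 4)).astype(np.float32))
        gate = Tensor(np.ones((1, 4, 1, 1, 1), np.float32))
        np.testing.assert_allclose((gate * a * b).data, a.data * b.data,
                                   atol=1e-6)
        zero = Tensor(np.zeros_like(a.data))
        assert np.abs((gate * zero * b).data).max() == 0

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            SAFNetConfig(base_channels=12)
        with pytest.raises(ValueError, match="num_classes"):
            SAFNetConfig(num_classes=1)
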