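"""Multi-kernel feature fusion: shapes, attention invariants, oracles."""

import numpy as np
import pytest

from m6afuse import autodiff as ad
from m6afuse.config import ConfigError, ModelConfig
from m6afuse.io_encoding import EncodedBatch
from m6afuse.mkff import (
    MKFF,
    ConcatFuse,
    EmbedProject,
    FeatureMap,
    GlobalChannelFusion,
    GLDFCombine,
    LocalSpatialFusion,
    MultiKernelExtract,
    adaptive_kernel_size,
)

import oracles
from conftest import random_codes


def _zero(layer_params):
    for p in layer_params:
        p.data[...] = 0.0


class TestAdaptiveKernelSize:
    @pytest.mark.parametrize("C,gamma,b,expected", [
        (128, 2, 1, 3),   # log2(128)/2 + 1/2 = 4.0 -> largest odd <= 4
        (2, 2, 1, 1),     # 0.5 + 0.5 = 1.0
        (1024, 2, 1, 5),  # 5.0 + 0.5 = 5.5
    ])
    def test_examples(self, C, gamma, b, expected):
        assert adaptive_kernel_size(C, gamma, b) == expected

    def test_exhaustive_odd_positive_monotone(self):
        previous = 0
        for C in range(2, 4097):
            k = adaptive_kernel_size(C, 2.0, 1.0)
            assert k >= 1 and k % 2 == 1
            assert k >= previous  # non-decreasing in channel count
            previous = k

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adaptive_kernel_size(0)
        with pytest.raises(ValueError):
            adaptive_kernel_size(8, gamma=0)


class TestEmbedProject:
    def test_shape_contract(self, rng):
        cfg = ModelConfig(L_max=800, out_channel=128)
        layer = EmbedProject(cfg, np.random.default_rng(0))
        codes = random_codes(rng, 2, 800)
        with ad.no_grad():
            out = layer(codes)
        assert out.shape == (2, 128, 800)

    def test_zero_projection_gives_zero_output(self, tiny_config, rng):
        layer = EmbedProject(tiny_config, np.random.default_rng(0))
        _zero(layer.project.parameters())
        with ad.no_grad():
            out = layer(random_codes(rng, 2, tiny_config.L_max))
        assert np.all(out.data == 0)

    def test_padding_code_embeds_to_zero(self, tiny_config):
        layer = EmbedProject(tiny_config, np.random.default_rng(0))
        assert np.all(layer.embedding.weight.data[0] == 0)

    def test_matches_dense_oracle(self, tiny_config, rng):
        layer = EmbedProject(tiny_config, np.random.default_rng(3))
        codes = random_codes(rng, 2, tiny_config.L_max)
        with ad.no_grad():
            out = layer(codes)
        table = layer.embedding.weight.data
        emb = table[codes].transpose(0, 2, 1)
        expected = oracles.conv1d_loops(emb, layer.project.weight.data,
                                        layer.project.bias.data)
        np.testing.assert_allclose(out.data, expected, atol=1e-6)


class TestMultiKernelExtract:
    def test_shapes_quarter_channels(self, rng):
        cfg = ModelConfig(L_max=800, out_channel=128)
        layer = MultiKernelExtract(cfg, np.random.default_rng(0))
        x = ad.Tensor(rng.standard_normal((2, 128, 800)).astype(np.float32))
        with ad.no_grad():
            paths = layer(x)
        for k in ("k1", "k2", "k3", "k4"):
            assert paths[k].shape == (2, 32, 800)

    def test_constant_input_pool_identity(self, tiny_config):
        # stride-1 pad-1 max pool of a constant map is that constant, so
        # k4 equals the point-wise convolution of the constant map
        layer = MultiKernelExtract(tiny_config, np.random.default_rng(1))
        const = np.full((1, 8, 12), 0.7)
        with ad.no_grad():
            paths = layer(ad.Tensor(const))
            direct = ad.relu(layer.k4(ad.Tensor(const)))
        np.testing.assert_allclose(paths["k4"].data, direct.data, atol=1e-12)

    def test_matches_loop_oracles(self, tiny_config, rng):
        layer = MultiKernelExtract(tiny_config, np.random.default_rng(2))
        x = rng.standard_normal((2, 8, 12))
        with ad.no_grad():
            paths = layer(ad.Tensor(x))
        r = oracles.relu_loops
        k1 = r(oracles.conv1d_loops(x, layer.k1.weight.data, layer.k1.bias.data))
        np.testing.assert_allclose(paths["k1"].data, k1, atol=1e-6)
        bottleneck = r(oracles.conv1d_loops(x, layer.k2_bottleneck.weight.data,
                                            layer.k2_bottleneck.bias.data))
        k2 = r(oracles.conv1d_loops(bottleneck, layer.k2.weight.data,
                                    layer.k2.bias.data, pad=1))
        np.testing.assert_allclose(paths["k2"].data, k2, atol=1e-6)
        bottleneck3 = r(oracles.conv1d_loops(x, layer.k3_bottleneck.weight.data,
                                             layer.k3_bottleneck.bias.data))
        k3 = r(oracles.conv1d_loops(bottleneck3, layer.k3.weight.data,
                                    layer.k3.bias.data, pad=2))
        np.testing.assert_allclose(paths["k3"].data, k3, atol=1e-6)
        pooled = oracles.maxpool1d_loops(x, 3, 1, 1)
        k4 = r(oracles.conv1d_loops(pooled, layer.k4.weight.data, layer.k4.bias.data))
        np.testing.assert_allclose(paths["k4"].data, k4, atol=1e-6)


class TestGlobalChannelFusion:
    def test_zero_conv_gives_half_weights(self, tiny_config, rng):
        layer = GlobalChannelFusion(tiny_config, np.random.default_rng(0))
        _zero(layer.parameters())
        mk = ad.Tensor(rng.standard_normal((2, 8, 12)))
        with ad.no_grad():
            weight, fea = layer(mk)
        np.testing.assert_allclose(weight.data, 0.5)  # sigmoid(0)
        np.testing.assert_allclose(fea.data, 0.5 * mk.data, atol=1e-12)

    def test_weights_in_sigmoid_range(self, tiny_config, rng):
        layer = GlobalChannelFusion(tiny_config, np.random.default_rng(1))
        with ad.no_grad():
            weight, _ = layer(ad.Tensor(rng.standard_normal((3, 8, 12))))
        assert np.all(weight.data > 0) and np.all(weight.data < 1)
        assert weight.shape == (3, 8, 1)

    def test_matches_loop_oracle(self, tiny_config, rng):
        layer = GlobalChannelFusion(tiny_config, np.random.default_rng(2))
        mk = rng.standard_normal((2, 8, 12))
        with ad.no_grad():
            weight, fea = layer(ad.Tensor(mk))
        ow, ofea = oracles.global_attention_loops(
            mk, layer.conv.weight.data, layer.conv.bias.data)
        np.testing.assert_allclose(weight.data[:, :, 0], ow, atol=1e-6)
        np.testing.assert_allclose(fea.data, ofea, atol=1e-6)


class TestLocalSpatialFusion:
    def test_zero_excitation_gives_uniform_weights(self, tiny_config, rng):
        layer = LocalSpatialFusion(tiny_config, np.random.default_rng(0))
        _zero(layer.excitation.parameters())
        mk = ad.Tensor(rng.standard_normal((2, 8, 12)))
        with ad.no_grad():
            weight, fea = layer(mk)
        np.testing.assert_allclose(weight.data, 1.0 / 12, atol=1e-12)
        np.testing.assert_allclose(fea.data, mk.data / 12, atol=1e-12)

    def test_softmax_rows_sum_to_one(self, tiny_config, rng):
        layer = LocalSpatialFusion(tiny_config, np.random.default_rng(1))
        with ad.no_grad():
            weight, _ = layer(ad.Tensor(rng.standard_normal((3, 8, 12))))
        np.testing.assert_allclose(weight.data.sum(axis=2), 1.0, atol=1e-5)

    def test_matches_loop_oracle(self, tiny_config, rng):
        layer = LocalSpatialFusion(tiny_config, np.random.default_rng(2))
        mk = rng.standard_normal((2, 8, 12))
        with ad.no_grad():
            weight, fea = layer(ad.Tensor(mk))
        ow, ofea = oracles.local_attention_loops(
            mk, layer.squeeze.weight.data, layer.squeeze.bias.data,
            layer.excitation.weight.data, layer.excitation.bias.data)
        np.testing.assert_allclose(weight.data, ow, atol=1e-6)
        np.testing.assert_allclose(fea.data, ofea, atol=1e-6)

    def test_indivisible_ratio_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(out_channel=8, reduction_ratio=3)


class TestMKFFComposition:
    def test_length_preservation_all_stages(self, tiny_config, rng):
        stack = MKFF(tiny_config, np.random.default_rng(0))
        taps = {}
        with ad.no_grad():
            stack(random_codes(rng, 2, tiny_config.L_max), taps=taps)
        for name in ("o_embed", "mk_fea", "o_mkff"):
            assert taps[name].shape[2] == tiny_config.L_max

    def test_residual_identity_when_combine_zeroed(self, tiny_config, rng):
        stack = MKFF(tiny_config, np.random.default_rng(0))
        _zero(stack.gldf.combine.parameters())
        taps = {}
        with ad.no_grad():
            out = stack(random_codes(rng, 2, tiny_config.L_max), taps=taps)
        np.testing.assert_array_equal(out.data, taps["o_embed"].data)

    def test_cat_variant_passes_mk_fea(self, rng):
        cfg = ModelConfig(L_max=12, embed_dim=3, out_channel=8, n_dr_blocks=2,
                          fusion_mode="cat", dtype="float64")
        stack = MKFF(cfg, np.random.default_rng(0))
        taps = {}
        codes = random_codes(rng, 2, 12)
        with ad.no_grad():
            out = stack(codes, taps=taps)
        np.testing.assert_allclose(
            out.data, taps["o_embed"].data + taps["mk_fea"].data, atol=1e-12)

    def test_add_variant_uses_sum_of_weighted_maps(self, rng):
        cfg = ModelConfig(L_max=12, embed_dim=3, out_channel=8, n_dr_blocks=2,
                          fusion_mode="add", dtype="float64")
        stack = MKFF(cfg, np.random.default_rng(0))
        codes = random_codes(rng, 2, 12)
        with ad.no_grad():
            out = stack(codes)
            # reproduce by hand: weighted maps -> sum -> combine conv -> residual
            o_embed = stack.embed(codes)
            mk = stack.concat_fuse(stack.extract(o_embed))
            _, gfea = stack.global_fusion(mk)
            _, lfea = stack.local_fusion(mk)
            expected = (o_embed + ad.relu(stack.gldf.combine(gfea + lfea))).data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_kernel_subset_combo(self, rng):
        cfg = ModelConfig(L_max=12, embed_dim=3, out_channel=8, n_dr_blocks=2,
                          kernel_combo=("k1", "k2"), dtype="float64")
        stack = MKFF(cfg, np.random.default_rng(0))
        assert stack.concat_fuse.fuse.weight.shape == (8, 4, 1)  # 2 paths x C/4 in
        with ad.no_grad():
            out = stack(random_codes(rng, 2, 12))
        assert out.shape == (2, 8, 12)

    def test_empty_combo_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(kernel_combo=())

    def test_default_matches_chained_oracles(self, tiny_config, rng):
        """End-to-end tiny-config check against the explicit-loop pipeline."""
        stack = MKFF(tiny_config, np.random.default_rng(4))
        codes = random_codes(rng, 2, tiny_config.L_max)
        with ad.no_grad():
            out = stack(codes)

        r = oracles.relu_loops
        table = stack.embed.embedding.weight.data
        emb = table[codes].transpose(0, 2, 1)
        o_embed = oracles.conv1d_loops(emb, stack.embed.project.weight.data,
                                       stack.embed.project.bias.data)
        ex = stack.extract
        k1 = r(oracles.conv1d_loops(o_embed, ex.k1.weight.data, ex.k1.bias.data))
        k2 = r(oracles.conv1d_loops(
            r(oracles.conv1d_loops(o_embed, ex.k2_bottleneck.weight.data,
                                   ex.k2_bottleneck.bias.data)),
            ex.k2.weight.data, ex.k2.bias.data, pad=1))
        k3 = r(oracles.conv1d_loops(
            r(oracles.conv1d_loops(o_embed, ex.k3_bottleneck.weight.data,
                                   ex.k3_bottleneck.bias.data)),
            ex.k3.weight.data, ex.k3.bias.data, pad=2))
        k4 = r(oracles.conv1d_loops(oracles.maxpool1d_loops(o_embed, 3, 1, 1),
                                    ex.k4.weight.data, ex.k4.bias.data))
        cat = np.concatenate([k1, k2, k3, k4], axis=1)
        mk = r(oracles.conv1d_loops(cat, stack.concat_fuse.fuse.weight.data,
                                    stack.concat_fuse.fuse.bias.data))
        gw, gfea = oracles.global_attention_loops(
            mk, stack.global_fusion.conv.weight.data, stack.global_fusion.conv.bias.data)
        lw, lfea = oracles.local_attention_loops(
            mk, stack.local_fusion.squeeze.weight.data, stack.local_fusion.squeeze.bias.data,
            stack.local_fusion.excitation.weight.data, stack.local_fusion.excitation.bias.data)
        fused = np.concatenate([gfea, lfea], axis=1)
        gldf = r(oracles.conv1d_loops(fused, stack.gldf.combine.weight.data,
                                      stack.gldf.combine.bias.data))
        np.testing.assert_allclose(out.data, o_embed + gldf, atol=1e-6)


def test_feature_map_rejects_nonfinite():
    with pytest.raises(ValueError):
        FeatureMap(np.array([[[np.nan]]]), "O_embed")
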