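"""Multi-scale block construction, enumeration, variants, and parameter
accounting, each checked against independent closed-form or brute-force
oracles."""

import itertools

import numpy as np
import pytest

from msunet import nn
from msunet.blocks import (KernelSpec, MSBlockConfig, MultiScaleBlock,
                           SerialBlock, build_block, build_conv_branch,
                           config_from_name, count_parameters, dilated_variant,
                           enumerate_block_configs, make_block)


def _zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestKernelSpec:
    def test_valid_sizes_only(self):
        for s in (1, 2, 3, 5, 7, 9):
            KernelSpec(s)
        with pytest.raises(ValueError):
            KernelSpec(4)
        with pytest.raises(ValueError):
            KernelSpec(3, dilation=0)

    def test_receptive_width(self):
        assert KernelSpec(3, dilation=3).receptive_width == 7
        assert KernelSpec(9).receptive_width == 9


class TestEnumeration:
    def test_exactly_31_configs(self):
        assert len(enumerate_block_configs()) == 31

    def test_names_are_subsets_of_123579_containing_3(self):
        names = {c.name for c in enumerate_block_configs()}
        expected = set()
        for r in range(1, 6):
            for combo in itertools.combinations("12579", r):
                expected.add("".join(sorted(combo + ("3",))))
        assert names == expected
        assert "37" in names and "123579" in names

    def test_two_kernel_configs(self):
        pairs = sorted(c.name for c in enumerate_block_configs() if len(c.kernels) == 2)
        assert pairs == ["13", "23", "35", "37", "39"]

    def test_all_parallel_concat_nonresidual(self):
        for c in enumerate_block_configs():
            assert (c.topology, c.fusion, c.residual) == ("parallel", "concat", "none")
            assert any(k.size == 3 for k in c.kernels)


class TestConvBranch:
    def test_shape_contract(self, rng):
        nn.manual_seed(0)
        branch = build_conv_branch(KernelSpec(3), 8, 16)
        x = nn.Tensor(rng.normal(size=(1, 8, 32, 32)).astype(np.float32))
        assert branch(x).shape == (1, 16, 32, 32)

    def test_zero_weights_give_zero_output(self, rng):
        nn.manual_seed(0)
        branch = build_conv_branch(KernelSpec(3), 4, 4, norm=False)
        _zero_params(branch)
        x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        assert np.all(branch(x).data == 0.0)

    def test_parameter_count_closed_form(self):
        # 3*3*8*16+16 convs: first in->out, second out->out
        nn.manual_seed(0)
        branch = build_conv_branch(KernelSpec(3), 8, 16, norm=False)
        assert branch.num_parameters() == (9 * 8 * 16 + 16) + (9 * 16 * 16 + 16) == 3488

    def test_rejects_bad_kernel(self):
        with pytest.raises(ValueError):
            build_conv_branch(KernelSpec(4), 4, 4)


class TestMultiScaleForward:
    def test_shape_and_concat_width(self, rng):
        cfg = config_from_name("37", 64, 64)
        nn.manual_seed(0)
        block = MultiScaleBlock(cfg)
        # fusion conv consumes the 128-channel concatenation of two branches
        assert block.fusion_conv.in_channels == 128
        x = nn.Tensor(rng.normal(size=(2, 64, 48, 48)).astype(np.float32))
        assert block(x).shape == (2, 64, 48, 48)

    def test_channel_mismatch_rejected(self, rng):
        nn.manual_seed(0)
        block = make_block("37", 8, 8)
        with pytest.raises(ValueError):
            block(nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32)))

    def test_single_branch_equals_branch_plus_fusion(self, rng):
        """Degenerate one-kernel block: branch output feeds the 1x1 directly."""
        cfg = config_from_name("3", 4, 4, norm=False)
        nn.manual_seed(5)
        block = MultiScaleBlock(cfg)
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        manual = block.fuse(block.branches[0](x))
        np.testing.assert_array_equal(block(x).data, manual.data)

    def test_zero_weights_fusion_bias_constant_map(self, rng):
        cfg = config_from_name("37", 4, 6, norm=False)
        nn.manual_seed(0)
        block = MultiScaleBlock(cfg)
        _zero_params(block)
        block.fusion_conv.bias.data[...] = 2.5
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, 2.5)  # ReLU passes +2.5

    def test_branches_do_not_share_weights(self, rng):
        nn.manual_seed(0)
        block = make_block("37", 4, 4)
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        before = block(x).data.copy()
        first_conv = block.branches[1].layers[0].layers[0]
        first_conv.weight.data += 0.5
        after = block(x).data
        assert not np.array_equal(before, after)

    def test_sum_fusion_keeps_branch_width(self, rng):
        cfg = config_from_name("37+sum", 8, 8)
        nn.manual_seed(0)
        block = MultiScaleBlock(cfg)
        assert block.fusion_conv.in_channels == 8
        x = nn.Tensor(rng.normal(size=(1, 8, 32, 32)).astype(np.float32))
        assert block(x).shape == (1, 8, 32, 32)

    def test_gradient_reaches_every_branch(self, rng):
        nn.manual_seed(0)
        block = make_block("137", 3, 5)
        x = nn.Tensor(rng.normal(size=(2, 3, 16, 16)).astype(np.float32))
        loss = nn.mean(nn.mul(block(x), block(x)))
        loss.backward()
        for name, p in block.named_parameters():
            assert p.grad is not None, name
            assert np.any(p.grad != 0) or p.data.size == 0, name


class TestSerialBlocks:
    def test_order_matters_but_contract_holds(self, rng):
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        nn.manual_seed(1)
        b37 = make_block("37+concatenated", 4, 8)
        nn.manual_seed(1)
        b73 = make_block("73+concatenated", 4, 8)
        y37, y73 = b37(x), b73(x)
        assert y37.shape == y73.shape == (1, 8, 16, 16)
        assert not np.array_equal(y37.data, y73.data)  # distinct parameterizations

    def test_same_kernel_twice_is_plain_deep_block(self):
        nn.manual_seed(0)
        block = make_block("33+concatenated", 4, 4)
        convs = [m for m in block.modules() if isinstance(m, nn.Conv2d)]
        assert len(convs) == 4 and all(c.kernel == 3 for c in convs)

    def test_zero_weights_zero_output(self, rng):
        cfg = config_from_name("37+concatenated", 4, 4, norm=False)
        nn.manual_seed(0)
        block = SerialBlock(cfg)
        _zero_params(block)
        x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        assert np.all(block(x).data == 0)

    def test_serial_requires_two_kernels(self):
        with pytest.raises(ValueError):
            config_from_name("357+concatenated", 4, 4)


class TestDilatedVariant:
    def test_replaces_7x7_with_dilated_3x3(self):
        cfg = config_from_name("37", 8, 8)
        d = dilated_variant(cfg)
        assert d.kernels == (KernelSpec(3, 1), KernelSpec(3, 3))
        assert d.kernels[1].receptive_width == 7

    def test_fewer_parameters_than_dense(self):
        cfg = config_from_name("37", 8, 8)
        assert count_parameters(dilated_variant(cfg)) < count_parameters(cfg)

    def test_requires_dense_7x7(self):
        with pytest.raises(ValueError):
            dilated_variant(config_from_name("35", 8, 8))


class TestResidualBlocks:
    def test_concat1_fusion_width_includes_input(self):
        cfg = config_from_name("res1:37", 64, 64)
        nn.manual_seed(0)
        block = MultiScaleBlock(cfg)
        assert block.fusion_conv.in_channels == 192  # 64 + 2*64

    def test_additive_identity_with_zero_block_path(self, rng):
        nn.manual_seed(0)
        block = make_block("res0:37", 8, 8)
        _zero_params(block)
        x = nn.Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)  # bitwise identity

    def test_additive_projects_on_channel_mismatch(self, rng):
        nn.manual_seed(0)
        block = make_block("res0:37", 4, 8)
        assert isinstance(block.project, nn.Conv2d)
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        assert block(x).shape == (1, 8, 16, 16)

    def test_concat1_zero_fusion_constant_map(self, rng):
        cfg = config_from_name("res1:37", 4, 4, norm=False)
        nn.manual_seed(0)
        block = MultiScaleBlock(cfg)
        _zero_params(block)
        block.fusion_conv.bias.data[...] = 1.5
        x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, 1.5)

    def test_residual_requires_parallel(self):
        with pytest.raises(ValueError):
            MSBlockConfig(kernels=(KernelSpec(3), KernelSpec(7)), in_channels=4,
                          out_channels=4, topology="serial", residual="additive_0")


class TestParameterCount:
    def test_minimal_closed_form(self):
        cfg = MSBlockConfig(kernels=(KernelSpec(3),), in_channels=1,
                            out_channels=1, norm=False)
        assert count_parameters(cfg) == 22  # 9+1 + 9+1 + (1+1)

    def test_monotone_in_kernel_set(self):
        a = config_from_name("3", 8, 8)
        b = config_from_name("37", 8, 8)
        assert count_parameters(b) > count_parameters(a)

    @pytest.mark.parametrize("name", ["37", "37+sum", "37+concatenated",
                                      "37+dilated", "res0:37", "res1:37",
                                      "res0:137"])
    def test_matches_built_module_walk(self, name):
        cfg = config_from_name(name, 8, 16)
        nn.manual_seed(0)
        assert count_parameters(cfg) == build_block(cfg).num_parameters()

    def test_all_31_configs_match_walk(self):
        for cfg in enumerate_block_configs(8, 16):
            nn.manual_seed(0)
            assert count_parameters(cfg) == build_block(cfg).num_parameters(), cfg.name


class TestFactory:
    @pytest.mark.parametrize("name", ["37", "37+sum", "37+concatenated",
                                      "73+concatenated", "37+dilated",
                                      "res0:37", "res1:37", "123579"])
    def test_names_resolve(self, name, rng):
        nn.manual_seed(0)
        block = make_block(name, 4, 4)
        x = nn.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        assert block(x).shape == (1, 4, 16, 16)

    def test_unknown_names_rejected(self):
        for bad in ("", "abc", "37+weird", "res2:37", "res0:37+concatenated"):
            with pytest.raises(ValueError):
                config_from_name(bad, 4, 4)
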