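"""Parallel Vision Mamba layer: split semantics, branch locality,
degenerate parallelism and the analytic reduction ratios."""

import numpy as np
import pytest

from ultralight_vmunet import (AccountingMode, ParallelVSS, PVMConfig,
                               PVMLayer, parallel_reduction_ratio,
                               split_channels)
from ultralight_vmunet.nn import Tensor, concat


class TestSplitChannels:
    def test_split_concat_roundtrip(self, rng):
        x = Tensor(rng.standard_normal((2, 5, 8)))
        parts = split_channels(x, 4)
        assert [p.shape for p in parts] == [(2, 5, 2)] * 4
        np.testing.assert_array_equal(concat(parts, axis=-1).data, x.data)

    def test_k1_is_identity(self, rng):
        x = Tensor(rng.standard_normal((1, 3, 64)))
        (part,) = split_channels(x, 1)
        np.testing.assert_array_equal(part.data, x.data)

    def test_indivisible_channels_raise(self, rng):
        with pytest.raises(ValueError):
            split_channels(Tensor(rng.standard_normal((1, 3, 6))), 4)


class TestPVMLayer:
    def test_output_shape_and_channel_change(self, rng):
        layer = PVMLayer.create(16, 24, k=4)
        x = rng.standard_normal((2, 10, 16)).astype(np.float32)
        assert layer(x).shape == (2, 10, 24)

    def test_k1_equals_directly_composed_single_vm(self, rng):
        """k=1 degenerates to LN -> (Mamba + theta*x) -> LN -> proj."""
        layer = PVMLayer.create(8, 8, k=1)
        x = Tensor(rng.standard_normal((2, 6, 8)).astype(np.float32))
        xn = layer.norm(x)
        vm = layer.mamba(xn) + layer.theta * xn
        expected = layer.proj(layer.norm(vm))
        np.testing.assert_allclose(layer(x).data, expected.data, rtol=1e-6)

    def test_branch_locality_before_concat(self, rng):
        """Perturbing the channels of group 2 leaves the other groups'
        pre-concat outputs unchanged."""
        layer = PVMLayer.create(16, 16, k=4)

        def branch_outputs(x):
            xn = layer.norm(Tensor(x))
            return [(layer.mamba(p) + layer.theta * p).data
                    for p in split_channels(xn, 4)]

        x = rng.standard_normal((1, 7, 16)).astype(np.float64)
        base = branch_outputs(x)
        x2 = x.copy()
        x2[:, 3, 4:8] += 0.5  # group 2 owns channels 4:8
        # perturbation changes the pre-LN statistics, so compare the branch
        # map on identical normalised inputs instead: bypass the shared LN
        xn = layer.norm(Tensor(x)).data
        xn2 = xn.copy()
        xn2[:, 3, 4:8] += 0.5
        outs = [(layer.mamba(p) + layer.theta * p).data
                for p in split_channels(Tensor(xn), 4)]
        outs2 = [(layer.mamba(p) + layer.theta * p).data
                 for p in split_channels(Tensor(xn2), 4)]
        for g in (0, 2, 3):
            np.testing.assert_array_equal(outs[g], outs2[g])
        assert not np.allclose(outs[1], outs2[1])
        assert len(base) == 4

    def test_group_permutation_equivariance(self, rng):
        """With shared branch weights, permuting whole channel groups of the
        normalised input permutes the pre-projection outputs accordingly."""
        layer = PVMLayer.create(16, 16, k=4)
        xn = rng.standard_normal((1, 5, 16))
        perm = [2, 0, 3, 1]

        def branches(arr):
            return [(layer.mamba(p) + layer.theta * p).data
                    for p in split_channels(Tensor(arr), 4)]

        outs = branches(xn)
        permuted = np.concatenate([xn[..., 4 * g:4 * g + 4] for g in perm], axis=-1)
        outs_p = branches(permuted)
        for i, g in enumerate(perm):
            np.testing.assert_allclose(outs_p[i], outs[g], rtol=1e-12)

    def test_zeroed_mamba_reduces_to_theta_residual_path(self, rng):
        """With the Mamba output projection zeroed, the layer computes
        proj(LN(theta * LN(x)))."""
        layer = PVMLayer.create(8, 4, k=4)
        layer.mamba.out_proj.weight.data = np.zeros_like(
            layer.mamba.out_proj.weight.data)
        x = Tensor(rng.standard_normal((2, 6, 8)).astype(np.float32))
        expected = layer.proj(layer.norm(layer.theta * layer.norm(x)))
        np.testing.assert_allclose(layer(x).data, expected.data, rtol=1e-5,
                                   atol=1e-7)

    def test_invalid_parallelism_raises(self):
        with pytest.raises(ValueError):
            PVMConfig(in_channels=6, out_channels=6, k=4)
        with pytest.raises(ValueError):
            PVMConfig(in_channels=8, out_channels=8, k=3)

    def test_independent_branches_have_k_mamba_copies(self):
        shared = PVMLayer.create(16, 16, k=4)
        indep = PVMLayer.create(16, 16, k=4, shared_branches=False)
        n_shared = shared.num_parameters()
        n_indep = indep.num_parameters()
        # 3 extra Mamba blocks and 3 extra thetas
        per_branch = shared.mamba.num_parameters() + 1
        assert n_indep == n_shared + 3 * per_branch


class TestParallelVSS:
    def test_k1_identical_to_inner_vss_block(self, rng):
        wrap = ParallelVSS(8, k=1)
        x = Tensor(rng.standard_normal((1, 8, 4, 4)).astype(np.float32))
        np.testing.assert_array_equal(wrap(x).data, wrap.vss(x).data)

    def test_spatial_shape_preserved(self, rng):
        wrap = ParallelVSS(16, k=4)
        x = rng.standard_normal((1, 16, 8, 8)).astype(np.float32)
        assert wrap(x).shape == (1, 16, 8, 8)

    def test_indivisible_channels_raise(self):
        with pytest.raises(ValueError):
            ParallelVSS(6, k=4)


class TestReductionRatios:
    def test_identity_at_k1(self):
        assert parallel_reduction_ratio(1024, 1) == 1.0

    def test_half_channel_ratio_rounds_to_published_value(self):
        assert round(parallel_reduction_ratio(1024, 2), 3) == 0.502

    def test_quarter_channel_ratio(self):
        # 4 * 1,484,288 / 23,435,264
        assert round(parallel_reduction_ratio(1024, 4), 4) == 0.2533

    def test_ss2d_quarter_channel_ratio(self):
        # 4 * 2,921,984 / 45,504,512
        assert round(parallel_reduction_ratio(1024, 4, counter="ss2d"), 4) == 0.2569

    def test_ratio_strictly_decreasing_in_k(self):
        for C in (64, 256, 1024):
            ratios = [parallel_reduction_ratio(C, k) for k in (1, 2, 4)]
            assert ratios[0] > ratios[1] > ratios[2]

    def test_ratio_tends_to_one_over_k(self):
        for k in (2, 4):
            assert abs(k * parallel_reduction_ratio(2 ** 16, k) - 1.0) < 0.02

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            parallel_reduction_ratio(1022, 4)
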