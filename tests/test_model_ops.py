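"""Model operators against brute-force loop oracles, and the dilation-set
design rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_cbam, naive_conv2d, naive_deform_conv2d, naive_msaa
from stemseg import nn
from stemseg.model import (
    CASPP,
    CBAM,
    MSAA,
    DilationSet,
    GriddingError,
    ModelConfig,
    c_aspp,
    cbam,
    effective_receptive_field,
    msaa,
    validate_dilation_set,
)
from stemseg.nn import Tensor


class TestReceptiveFieldAndRates:
    @pytest.mark.parametrize("k,r,expected", [(3, 1, 3), (3, 6, 13), (3, 15, 31), (5, 2, 9)])
    def test_effective_receptive_field(self, k, r, expected):
        assert effective_receptive_field(k, r) == expected

    @pytest.mark.parametrize("k,r", [(0, 1), (3, 0), (-3, 2), (4, 2)])
    def test_invalid_kernel_or_rate(self, k, r):
        with pytest.raises(ValueError):
            effective_receptive_field(k, r)

    @pytest.mark.parametrize(
        "rates,gcd,ok",
        [
            ((1, 2, 7, 15), 1, True),  # the network's default pyramid
            ((2, 4, 8), 2, False),
            ((6, 12, 18), 6, False),  # the classic three-rate pyramid
            ((1, 3, 6, 12), 1, True),
            ((5,), 5, False),
        ],
    )
    def test_gcd_criterion(self, rates, gcd, ok):
        g, passed = validate_dilation_set(rates)
        assert (g, passed) == (gcd, ok)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=6))
    def test_gcd_matches_euclid_oracle(self, rates):
        g, passed = validate_dilation_set(tuple(rates))
        expected = math.gcd(*rates) if len(rates) > 1 else rates[0]
        assert g == expected and passed == (expected == 1)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            validate_dilation_set(())
        with pytest.raises(ValueError):
            DilationSet(())

    def test_rates_must_increase(self):
        with pytest.raises(ValueError):
            DilationSet((2, 2, 7))


class TestDeformableConv:
    @pytest.mark.parametrize("stride", [1, 2])
    def test_zero_offsets_reduce_to_standard_convolution(self, stride):
        rng = np.random.default_rng(0)
        x = Tensor(rng.normal(size=(2, 3, 8, 8)).astype(np.float32))
        w = Tensor(rng.normal(size=(4, 3, 3, 3)).astype(np.float32))
        b = Tensor(rng.normal(size=4).astype(np.float32))
        ref = nn.conv2d(x, w, b, stride, 1, 1)
        off = Tensor(np.zeros((2, 18, *ref.shape[2:]), dtype=np.float32))
        out = nn.deform_conv2d(x, w, off, b, stride, 1, 1)
        assert np.abs(out.data - ref.data).max() <= 1e-5

    def test_integer_offset_shifts_the_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 2, 10, 10))
        w = rng.normal(size=(3, 2, 3, 3))
        shifted = np.roll(x, shift=(0, -1), axis=(2, 3))  # offset (0, +1) gathers col+1
        ref = nn.conv2d(Tensor(shifted), Tensor(w), None, 1, 1, 1)
        off = np.zeros((1, 18, 10, 10))
        off[:, 1::2] = 1.0  # dx = +1 on every tap
        out = nn.deform_conv2d(Tensor(x), Tensor(w), Tensor(off), None, 1, 1, 1)
        # compare away from the wrap-around / zero-padding frontier
        interior = (slice(None), slice(None), slice(2, 8), slice(2, 8))
        assert np.abs(out.data[interior] - ref.data[interior]).max() <= 1e-5

    @pytest.mark.parametrize("stride,padding,dilation", [(1, 1, 1), (2, 1, 1), (1, 2, 2)])
    def test_random_offsets_match_gather_loop_oracle(self, stride, padding, dilation):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, 1, 8, 8))
        w = rng.normal(size=(2, 1, 3, 3))
        b = rng.normal(size=2)
        out_hw = nn.conv2d(Tensor(x), Tensor(w), None, stride, padding, dilation).shape[2:]
        off = rng.uniform(-1.5, 1.5, size=(1, 18, *out_hw))
        ours = nn.deform_conv2d(Tensor(x), Tensor(w), Tensor(off), Tensor(b), stride, padding, dilation)
        oracle = naive_deform_conv2d(x, w, off, b, stride, padding, dilation)
        assert np.abs(ours.data - oracle).max() <= 1e-5

    def test_shape_mismatch_rejected(self):
        x = Tensor(np.zeros((1, 1, 8, 8)))
        w = Tensor(np.zeros((1, 1, 3, 3)))
        with pytest.raises(ValueError):
            nn.deform_conv2d(x, w, Tensor(np.zeros((1, 18, 5, 5))), None, 1, 1, 1)


class TestCbam:
    def test_output_shape_and_attention_ranges(self):
        nn.set_seed(20)
        block = CBAM(6, reduction=2)
        # float64 input: the open-interval property is checked in a precision
        # where the logistic cannot round to exactly 0 or 1
        x = Tensor(np.random.default_rng(0).normal(size=(2, 6, 5, 5)))
        out = block(x)
        assert out.shape == x.shape
        mc = block.channel(x)
        ms = block.spatial(x)
        assert ((mc.data > 0) & (mc.data < 1)).all()
        assert ((ms.data > 0) & (ms.data < 1)).all()

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 4, 4))
        block = CBAM(2, reduction=1)
        out = cbam(x, module=block)
        expected, mc, ms = naive_cbam(
            x,
            block.channel.fc1.weight.data,
            block.channel.fc1.bias.data,
            block.channel.fc2.weight.data,
            block.channel.fc2.bias.data,
            block.spatial.conv.weight.data,
            block.spatial.conv.bias.data,
        )
        assert np.abs(out.data - expected).max() <= 1e-5

    def test_functional_wrapper_preserves_shape(self):
        out = cbam(np.zeros((3, 6, 7), dtype=np.float32))
        assert out.shape == (3, 6, 7)


class TestMsaa:
    def test_zeroed_projection_gives_residual_passthrough(self):
        block = MSAA(5, reduction=4)
        block.project.weight.data[:] = 0.0
        block.project.bias.data[:] = 0.0
        x = np.random.default_rng(0).normal(size=(5, 6, 6)).astype(np.float32)
        out = msaa(x, module=block)
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_attention_map_shapes_and_ranges(self):
        nn.set_seed(21)
        block = MSAA(8, reduction=4)
        x = Tensor(np.random.default_rng(1).normal(size=(2, 8, 6, 6)))
        z = block.reduce(x)
        u = block.conv3(z) + block.conv5(z) + block.conv7(z)
        ws = block.spatial_gate(u)
        wc = block.channel_gate(u)
        assert ws.shape == (2, 1, 6, 6)
        assert wc.shape == (2, 4, 1, 1)
        assert ((ws.data > 0) & (ws.data < 1)).all()
        assert ((wc.data > 0) & (wc.data < 1)).all()

    def test_reduction_never_exceeds_input_channels(self):
        assert MSAA(4).d <= 4

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 6, 6))
        block = MSAA(4, reduction=2)
        out = msaa(x, module=block)
        expected, ws, wc = naive_msaa(x, block)
        assert np.abs(out.data - expected).max() <= 1e-5


class TestCaspp:
    def test_six_parallel_branches_for_four_rates(self):
        cfg = ModelConfig(width_mult=0.125)
        block = CASPP(8, 8, cfg)
        assert len(block.branches) == 6  # 4 atrous + 1x1 + image pooling

    def test_spatial_size_preserved(self):
        cfg = ModelConfig(width_mult=0.125)
        out = c_aspp(np.random.default_rng(0).normal(size=(8, 9, 9)).astype(np.float32), cfg)
        assert out.shape[1:] == (9, 9)

    def test_atrous_branch_impulse_matches_direct_dilation_loop(self):
        rng = np.random.default_rng(5)
        x = np.zeros((1, 1, 9, 9))
        x[0, 0, 4, 4] = 1.0  # unit impulse
        w = rng.normal(size=(1, 1, 3, 3))
        ours = nn.conv2d(Tensor(x), Tensor(w), None, 1, 2, 2)
        oracle = naive_conv2d(x, w, None, 1, 2, 2)
        assert np.abs(ours.data - oracle).max() <= 1e-5

    def test_gridding_rates_rejected_in_strict_mode(self):
        with pytest.raises(GriddingError):
            ModelConfig(aspp_rates=(2, 4, 8))
        cfg = ModelConfig(aspp_rates=(2, 4, 8), strict_rates=False)
        cfg.strict_rates = True  # block-level validation must also fire
        with pytest.raises(GriddingError):
            CASPP(8, 8, cfg)

    def test_relaxed_mode_allows_classic_rates(self):
        cfg = ModelConfig(aspp_rates=(6, 12, 18), strict_rates=False, width_mult=0.125)
        block = CASPP(8, 8, cfg)
        assert len(block.branches) == 5
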