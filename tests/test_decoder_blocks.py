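"""Decoder blocks: shuffle upsampling, multi-scale gating, channel attention
modulation, and branch fusion."""

import numpy as np
import pytest

from egunet import _tensor as F
from egunet._tensor import Tensor
from egunet.blocks import (CamBlock, CSUBlock, DualGate, MsagBlock,
                           MultiScaleConvBlock, channel_shuffle, fuse_branches,
                           shuffle_permutation)
from egunet.errors import ConfigError, ShapeError


# -- channel shuffle / CSU ---------------------------------------------------

def test_shuffle_permutation_matches_reshape_transpose_oracle():
    # oracle: reshape (g, C/g) -> transpose -> flatten
    for c, g in [(4, 2), (12, 3), (16, 4)]:
        oracle = np.arange(c).reshape(g, c // g).T.reshape(-1)
        np.testing.assert_array_equal(shuffle_permutation(c, g), oracle)
    np.testing.assert_array_equal(shuffle_permutation(4, 2), [0, 2, 1, 3])


def test_shuffle_then_inverse_recovers_input(rng):
    x = Tensor(rng.normal(size=(2, 12, 3, 3)))
    perm = shuffle_permutation(12, 3)
    inv = np.argsort(perm)
    y = F.take_channels(channel_shuffle(x, 3), inv)
    np.testing.assert_array_equal(y.data, x.data)


def test_shuffle_preserves_channel_multiset(rng):
    x = Tensor(rng.normal(size=(1, 8, 4, 4)))
    y = channel_shuffle(x, 2).data
    np.testing.assert_allclose(np.sort(y.sum(axis=(2, 3)).ravel()),
                               np.sort(x.data.sum(axis=(2, 3)).ravel()))


def test_csublock_doubles_space_and_is_nonnegative(rng):
    block = CSUBlock(8, 4, shuffle_groups=2, rng=rng)
    out = block(Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32)))
    assert out.shape == (1, 4, 32, 32)
    assert (out.data >= 0).all()


def test_csublock_group_divisibility_enforced():
    with pytest.raises(ConfigError):
        CSUBlock(8, 6, shuffle_groups=4)


# -- MCB ---------------------------------------------------------------------

def test_mcb_shape_and_zero_fixed_point(rng):
    mcb = MultiScaleConvBlock(16, 8, rng=rng)
    out = mcb(Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32)))
    assert out.shape == (1, 8, 8, 8)
    zero = mcb(Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)))
    np.testing.assert_array_equal(zero.data, 0.0)


def test_mcb_single_branch_equals_plain_separable_conv(rng):
    """With only the 3x3 branch, MCB is GELU(BN(dw3(pw(x)))) exactly."""
    mcb = MultiScaleConvBlock(6, 4, kernels=(3,), rng=rng).eval()
    x = Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32))
    expected = F.gelu(mcb.bn(mcb.dw3(mcb.project(x))))
    np.testing.assert_array_equal(mcb(x).data, expected.data)


# -- dual gate / MSAG --------------------------------------------------------

def test_dual_gate_zero_input_gives_center_values(rng):
    gate = DualGate(4, rng=rng)
    a, m = gate(Tensor(np.zeros((1, 4, 3, 3), dtype=np.float32)))
    np.testing.assert_allclose(a.data, 0.5)   # sigmoid(bias=0)
    np.testing.assert_allclose(m.data, 0.0)   # tanh(bias=0)


def test_dual_gate_codomains(rng):
    # float64 so the open-interval codomain survives rounding
    gate = DualGate(8, rng=rng)
    a, m = gate(Tensor(rng.normal(scale=3, size=(1, 8, 16, 16))))
    assert 0 < a.data.min() and a.data.max() < 1
    assert np.abs(m.data).max() < 1


def test_msag_output_channels_match_local_input(rng):
    block = MsagBlock(32, 16, 8, rng=rng).eval()
    g = Tensor(rng.normal(size=(1, 32, 8, 8)).astype(np.float32))
    x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    assert block(g, x).shape == (1, 16, 8, 8)


def test_msag_gate_bypass_identity(rng):
    """With A forced to 1 and M to 0 the gated transform passes x_lat through,
    so the block reduces to its output projection of x_lat."""
    block = MsagBlock(8, 8, 4, rng=rng).eval()
    g = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    x = Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
    out = block(g, x, forced_gates=(np.ones((1, 4, 6, 6), np.float32),
                                    np.zeros((1, 4, 6, 6), np.float32)))
    x_lat = block.lat_bn(block.lat(x))
    expected = block.out_bn(block.out(x_lat))
    np.testing.assert_allclose(out.data, expected.data, atol=1e-6)


def test_msag_gated_feature_bounded_by_twice_lateral(rng):
    """|Y| = |x_lat*(A+M)| <= 2|x_lat| since A in (0,1), M in (-1,1)."""
    block = MsagBlock(8, 8, 4, rng=rng).eval()
    g = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
    x = Tensor(rng.normal(size=(2, 8, 8, 8)).astype(np.float32))
    f = F.gelu(block.fuse_bn(block.fuse(F.add(block.mcb_g(g), block.mcb_x(x)))))
    a, m = block.gates(f)
    x_lat = block.lat_bn(block.lat(x))
    y = (x_lat.data * a.data) + (x_lat.data * m.data)
    assert (np.abs(y) <= 2 * np.abs(x_lat.data) + 1e-6).all()


def test_msag_spatial_mismatch_rejected(rng):
    block = MsagBlock(8, 8, 4, rng=rng)
    with pytest.raises(ShapeError):
        block(Tensor(np.zeros((1, 8, 6, 6), np.float32)),
              Tensor(np.zeros((1, 8, 4, 4), np.float32)))


# -- CAM ---------------------------------------------------------------------

def test_cam_layerscale_zero_is_exact_identity(rng):
    block = CamBlock(8, gn_groups=4, rng=rng).eval()
    block.gamma.data[:] = 0.0
    x = Tensor(rng.normal(size=(2, 8, 7, 7)).astype(np.float32))
    np.testing.assert_array_equal(block(x).data, x.data)


def test_cam_droppath_rate_one_drops_branch(rng):
    block = CamBlock(8, gn_groups=4, droppath_rate=1.0, rng=rng)
    block.train()
    x = Tensor(rng.normal(size=(2, 8, 5, 5)).astype(np.float32))
    np.testing.assert_array_equal(block(x).data, x.data)


def test_cam_se_scale_in_unit_interval(rng):
    block = CamBlock(16, gn_groups=4, rng=rng).eval()
    z = Tensor(rng.normal(scale=4, size=(3, 16, 6, 6)).astype(np.float32))
    s = block.se_scale(z).data
    assert s.shape == (3, 16, 1, 1)
    assert 0 < s.min() and s.max() < 1


def test_cam_kernel_validation():
    with pytest.raises(ConfigError):
        CamBlock(8, dw_kernel=4, gn_groups=4)


# -- fusion ------------------------------------------------------------------

def test_gated_fusion_zero_msag_halves_cam(rng):
    y_cam = Tensor(rng.normal(size=(1, 4, 5, 5)).astype(np.float32))
    zero = Tensor(np.zeros((1, 4, 5, 5), np.float32))
    out = fuse_branches(zero, y_cam, "gated_weighted_sum")
    np.testing.assert_allclose(out.data, 0.5 * y_cam.data, rtol=1e-6)


def test_gated_fusion_scalar_value():
    # msag = +10 everywhere, cam = 0: out = 10 * sigmoid(10) per element
    y_m = Tensor(np.full((1, 1, 2, 2), 10.0))
    y_c = Tensor(np.zeros((1, 1, 2, 2)))
    out = fuse_branches(y_m, y_c, "gated_weighted_sum")
    np.testing.assert_allclose(out.data, 10.0 / (1 + np.exp(-10.0)), rtol=1e-10)
    assert abs(out.data[0, 0, 0, 0] - 9.99955) < 1e-4


def test_gated_fusion_is_convex_combination(rng):
    y_m = Tensor(rng.normal(scale=3, size=(1, 8, 12, 12)))
    y_c = Tensor(rng.normal(scale=3, size=(1, 8, 12, 12)))
    out = fuse_branches(y_m, y_c, "gated_weighted_sum").data
    lo = np.minimum(y_m.data, y_c.data)
    hi = np.maximum(y_m.data, y_c.data)
    assert (out >= lo - 1e-9).all() and (out <= hi + 1e-9).all()


def test_elementwise_strategies_match_numpy_oracle(rng):
    a = Tensor(rng.normal(size=(1, 3, 4, 4)))
    b = Tensor(rng.normal(size=(1, 3, 4, 4)))
    np.testing.assert_array_equal(fuse_branches(a, b, "addition").data,
                                  a.data + b.data)
    np.testing.assert_array_equal(fuse_branches(a, b, "multiplication").data,
                                  a.data * b.data)


def test_unknown_strategy_rejected(rng):
    a = Tensor(np.zeros((1, 2, 2, 2)))
    with pytest.raises(ConfigError):
        fuse_branches(a, a, "averaging")


def test_concatenation_requires_projection(rng):
    a = Tensor(rng.normal(size=(1, 4, 3, 3)).astype(np.float32))
    with pytest.raises(ConfigError):
        fuse_branches(a, a, "concatenation")
    from egunet import nn
    proj = nn.Conv2d(8, 4, 1, rng=rng)
    assert fuse_branches(a, a, "concatenation", proj).shape == (1, 4, 3, 3)
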