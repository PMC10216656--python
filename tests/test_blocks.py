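"""Algebraic and structural checks for the decoupled conv operators and the
three residual-block topologies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p3dstage.blocks import (BlockConfig, ConvSpec, DilationSpec, P3DBlock,
                             apply_conv, block_forward, count_block_params,
                             effective_kernel_size, same_padding)
from p3dstage.errors import InvalidArgumentError, ShapeError


# ---------------------------------------------------------------------------
# dilation arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k,r,expected", [(3, 2, 5), (3, 1, 3), (1, 4, 1),
                                          (5, 3, 13), (7, 2, 13)])
def test_effective_kernel_size(k, r, expected):
    assert effective_kernel_size(k, r) == expected
    assert DilationSpec(k, r).K == expected


@pytest.mark.parametrize("k,r", [(0, 1), (2, 1), (4, 2), (3, 0), (3, -1)])
def test_effective_kernel_size_rejects_bad_args(k, r):
    with pytest.raises(InvalidArgumentError):
        effective_kernel_size(k, r)


@pytest.mark.parametrize("k,r,expected", [(3, 2, 2), (3, 1, 1), (1, 5, 0),
                                          (5, 2, 4)])
def test_same_padding(k, r, expected):
    assert same_padding(k, r) == expected


@given(k=st.sampled_from([1, 3, 5, 7]), r=st.integers(1, 6))
@settings(max_examples=50, deadline=None)
def test_dilation_law_properties(k, r):
    K = effective_kernel_size(k, r)
    assert K == r * (k - 1) + 1
    assert effective_kernel_size(k, 1) == k
    assert effective_kernel_size(1, r) == 1
    # with same padding and stride 1 the axis extent is preserved
    n = 11
    assert (n + 2 * same_padding(k, r) - K) + 1 == n


# ---------------------------------------------------------------------------
# apply_conv
# ---------------------------------------------------------------------------

def test_zero_input_gives_zero_output(rng):
    spec = ConvSpec.spatial(3, 4, 3, r=2)
    w = rng.normal(size=(4, 3, 1, 3, 3)).astype(np.float32)
    out = apply_conv(np.zeros((1, 3, 4, 8, 8), np.float32), spec, w)
    assert np.all(out == 0)


def test_temporal_impulse_response_support():
    """A dilated temporal kernel responds only at its dilated tap offsets."""
    spec = ConvSpec.temporal(1, 1, 3, r=2)
    w = np.ones((1, 1, 3, 1, 1), np.float32)
    x = np.zeros((1, 1, 9, 1, 1), np.float32)
    x[0, 0, 4] = 1.0  # unit impulse mid-sequence
    out = apply_conv(x, spec, w)[0, 0, :, 0, 0]
    assert set(np.nonzero(out)[0]) == {2, 4, 6}


@pytest.mark.parametrize("k,r", [(3, 1), (3, 2), (5, 2)])
def test_impulse_support_equals_effective_kernel_size(k, r):
    """Impulse-response support spans exactly K = r(k-1)+1 cells."""
    spec = ConvSpec.temporal(1, 1, k, r=r)
    w = np.ones((1, 1, k, 1, 1), np.float32)
    t = 4 * effective_kernel_size(k, r)
    x = np.zeros((1, 1, t, 1, 1), np.float32)
    x[0, 0, t // 2] = 1.0
    nz = np.nonzero(apply_conv(x, spec, w)[0, 0, :, 0, 0])[0]
    assert nz.max() - nz.min() + 1 == effective_kernel_size(k, r)
    assert len(nz) == k


def test_shape_contract_spatial(rng):
    spec = ConvSpec.spatial(4, 6, 3, r=2)
    x = rng.normal(size=(2, 4, 10, 16, 16)).astype(np.float32)
    out = apply_conv(x, spec, rng.normal(size=(6, 4, 1, 3, 3)).astype(np.float32))
    assert out.shape == (2, 6, 10, 16, 16)


def test_apply_conv_reports_both_shapes(rng):
    spec = ConvSpec.spatial(4, 6, 3)
    with pytest.raises(ShapeError):
        apply_conv(np.zeros((1, 3, 5, 8, 8), np.float32), spec,
                   np.zeros((6, 4, 1, 3, 3), np.float32))
    with pytest.raises(ShapeError):
        apply_conv(np.zeros((1, 4, 5, 8, 8), np.float32), spec,
                   np.zeros((6, 4, 3, 3, 3), np.float32))


def test_spatial_conv_commutes_with_time_permutation(rng):
    """Spatial convs treat frames independently."""
    spec = ConvSpec.spatial(2, 3, 3, r=2)
    w = rng.normal(size=(3, 2, 1, 3, 3)).astype(np.float32)
    x = rng.normal(size=(1, 2, 6, 9, 9)).astype(np.float32)
    perm = rng.permutation(6)
    assert np.allclose(apply_conv(x, spec, w)[:, :, perm],
                       apply_conv(x[:, :, perm], spec, w), atol=1e-6)


def test_temporal_conv_commutes_with_spatial_transpose(rng):
    """Temporal convs treat pixels independently."""
    spec = ConvSpec.temporal(2, 3, 3, r=2)
    w = rng.normal(size=(3, 2, 3, 1, 1)).astype(np.float32)
    x = rng.normal(size=(1, 2, 6, 9, 9)).astype(np.float32)
    assert np.allclose(apply_conv(x, spec, w).transpose(0, 1, 2, 4, 3),
                       apply_conv(x.transpose(0, 1, 2, 4, 3), spec, w),
                       atol=1e-6)


def test_dilated_equals_zero_inflated_dense(rng):
    """A dilated conv equals a dense conv with the zero-inflated kernel."""
    spec = ConvSpec.spatial(2, 2, 3, r=2)
    w = rng.normal(size=(2, 2, 1, 3, 3)).astype(np.float32)
    dense = np.zeros((2, 2, 1, 5, 5), np.float32)
    dense[:, :, :, ::2, ::2] = w
    dense_spec = ConvSpec("spatial", 2, 2, (1, 5, 5), padding=(0, 2, 2))
    x = rng.normal(size=(2, 2, 4, 10, 10)).astype(np.float32)
    assert np.allclose(apply_conv(x, spec, w), apply_conv(x, dense_spec, dense),
                       atol=1e-5)


# ---------------------------------------------------------------------------
# block topologies
# ---------------------------------------------------------------------------

def _dense3d_valid(x, kernel):
    """Brute-force dense 3D cross-correlation (same padding, stride 1)."""
    co, ci, kt, kh, kw = kernel.shape
    n, _, t, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kt // 2,) * 2, (kh // 2,) * 2,
                    (kw // 2,) * 2))
    out = np.zeros((n, co, t, h, w))
    for b in range(n):
        for o in range(co):
            for c in range(ci):
                for it in range(kt):
                    for ih in range(kh):
                        for iw in range(kw):
                            out[b, o] += kernel[o, c, it, ih, iw] * \
                                xp[b, c, it:it + t, ih:ih + h, iw:iw + w]
    return out


@pytest.mark.parametrize("variant", ["A", "B", "C"])
def test_zeroed_path_is_identity(rng, variant):
    """H(x) = F(x) + x collapses to the identity when F is zero."""
    cfg = BlockConfig(variant, in_channels=8, planes=2, expansion=4)
    block = P3DBlock(cfg, rng=rng, linear=True)
    for _, p in block.named_parameters():
        p.data[...] = 0.0
    x = rng.normal(size=(2, 8, 5, 6, 6)).astype(np.float32)
    assert np.array_equal(block.forward(x), x)


def test_linear_variant_a_equals_dense_separable_conv(rng):
    """Serial spatial∘temporal in linear mode is one dense 3D conv whose
    kernel is the channel-composed product of the two factors."""
    cfg = BlockConfig("A", in_channels=2, planes=2, expansion=1)
    block = P3DBlock(cfg, rng=rng, linear=True)
    eye = np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1, 1)
    block.reduce.conv.weight.data[...] = eye
    block.expand.conv.weight.data[...] = eye
    ws = block.spatial.conv.weight.data    # (2,2,1,3,3)
    wt = block.temporal.conv.weight.data   # (2,2,3,1,1)
    # composed dense kernel: k3[o,c,t,h,w] = sum_m wt[o,m,t] * ws[m,c,h,w]
    k3 = np.einsum("omt,mchw->octhw", wt[:, :, :, 0, 0], ws[:, :, 0])
    # dilation 1 here, so the dense oracle applies directly
    x = rng.normal(size=(1, 2, 6, 8, 8)).astype(np.float32)
    got = block.forward(x) - x
    want = _dense3d_valid(x.astype(np.float64), k3.astype(np.float64))
    assert np.allclose(got, want, atol=1e-5)


def test_linear_variant_b_additivity(rng):
    """With zeroed temporal weights, variant B reduces to the spatial branch."""
    cfg = BlockConfig("B", in_channels=4, planes=4, expansion=1)
    block = P3DBlock(cfg, rng=rng, linear=True)
    eye = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1, 1)
    block.reduce.conv.weight.data[...] = eye
    block.expand.conv.weight.data[...] = eye
    block.temporal.conv.weight.data[...] = 0.0
    x = rng.normal(size=(1, 4, 5, 7, 7)).astype(np.float32)
    spatial_only = apply_conv(
        x, ConvSpec.spatial(4, 4, 3), block.spatial.conv.weight.data)
    assert np.allclose(block.forward(x) - x, spatial_only, atol=1e-5)


@pytest.mark.parametrize("variant", ["A", "B", "C"])
def test_block_output_shape_and_projection(rng, variant):
    cfg = BlockConfig(variant, in_channels=8, planes=4, expansion=4,
                      stride=(1, 2, 2), spatial_dilation=2, temporal_dilation=2)
    block = P3DBlock(cfg, rng=rng)
    x = rng.normal(size=(2, 8, 10, 8, 8)).astype(np.float32)
    out = block.forward(x, train=True)
    assert out.shape == (2, 16, 10, 4, 4)


def test_block_forward_functional_wrapper(rng):
    cfg = BlockConfig("A", in_channels=4, planes=2, expansion=2)
    block = P3DBlock(cfg, rng=np.random.default_rng(7))
    x = rng.normal(size=(1, 4, 5, 6, 6)).astype(np.float32)
    out = block_forward(x, cfg, params=block.state_dict())
    assert np.array_equal(out, block.forward(x))


def test_block_channel_mismatch_raises(rng):
    cfg = BlockConfig("A", in_channels=8, planes=2)
    with pytest.raises(ShapeError):
        P3DBlock(cfg, rng=rng).forward(
            np.zeros((1, 4, 5, 6, 6), np.float32))


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def test_count_matches_instantiation(rng):
    for variant in "ABC":
        for cfg in [
            BlockConfig(variant, 64, 16, expansion=4),
            BlockConfig(variant, 64, 16, expansion=4, stride=(1, 2, 2)),
            BlockConfig(variant, 256, 64, expansion=4, include_temporal=False),
        ]:
            assert count_block_params(cfg) == P3DBlock(cfg, rng=rng).num_parameters()


def test_variants_have_identical_counts():
    cfgs = [BlockConfig(v, 32, 8) for v in "ABC"]
    counts = {count_block_params(c) for c in cfgs}
    assert len(counts) == 1


def test_dilation_does_not_change_count():
    base = count_block_params(BlockConfig("A", 32, 8))
    for r in (2, 3, 4):
        assert count_block_params(
            BlockConfig("A", 32, 8, spatial_dilation=r, temporal_dilation=r)
        ) == base


def test_decomposition_parameter_saving():
    """Spatial+temporal pair costs 12p^2 weights vs 27p^2 for dense 3x3x3."""
    p = 8
    decomposed = (ConvSpec.spatial(p, p, 3), ConvSpec.temporal(p, p, 3))
    n_dec = sum(s.out_channels * s.in_channels * np.prod(s.kernel)
                for s in decomposed)
    assert n_dec == 12 * p * p
    assert 27 * p * p == p * p * 3 * 3 * 3  # dense reference
    # trivial 1->1 dense conv with bias
    assert 27 + 1 == 28
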