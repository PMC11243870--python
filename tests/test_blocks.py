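"""Block-level contracts and explicit-loop oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import identity_bns, seed_params, single, t, zero_convs
from elanet.blocks import (CBAM, ChannelAttention, ContextBlock, Downsample,
                           FeatureFusion, PyramidPooling, SpatialAttention,
                           channel_shuffle, channel_split)
from elanet.nn.tensor import Tensor, concat, no_grad

TOL = dict(rtol=1e-5, atol=1e-6)


# -- downsample ------------------------------------------------------------

def test_downsample_paper_shapes():
    """3@1024x512 -> 32@512x256 -> 64@256x128, the published stage sizes."""
    d1 = Downsample(3, 32)
    assert d1.out_shape((3, 1024, 512)) == (32, 512, 256)
    d2 = Downsample(32, 64)
    assert d2.out_shape((32, 512, 256)) == (64, 256, 128)
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 64, 32)).astype(np.float32))
    assert d1(x).shape == (1, 32, 32, 16)


def test_downsample_rejects_nonexpanding_channels():
    with pytest.raises(ValueError, match="cin=8, cout=8"):
        Downsample(8, 8)


def test_downsample_pool_branch_matches_window_max_oracle(rng):
    """Conv branch zeroed + identity BN: the pooled channels reproduce the
    brute-force 2x2 window maxima (after ReLU)."""
    d = Downsample(3, 8)
    identity_bns(zero_convs(d))
    x = rng.normal(size=(3, 10, 8)).astype(np.float32)
    out = single(d(t(x)))
    expect = np.maximum(oracles.maxpool2x2_loop(x), 0)
    np.testing.assert_allclose(out[5:], expect, **TOL)  # pool branch: last cin channels
    np.testing.assert_allclose(out[:5], 0.0, **TOL)     # zeroed conv branch


# -- attention -------------------------------------------------------------

def test_channel_attention_shape_and_open_interval(rng):
    ca = seed_params(ChannelAttention(6, reduction=2), 3)
    out = ca(t(rng.normal(size=(6, 5, 7)) * 30))
    assert out.shape == (1, 6, 1, 1)
    assert (out.data > 0).all() and (out.data < 1).all()


def test_channel_attention_constant_map_identity_perceptron():
    """Spatially constant F: avg and max pools agree, so the gate equals
    sigmoid(2 * MLP(v)); with an identity perceptron that is sigmoid(2v)."""
    ca = ChannelAttention(3, reduction=1, bias=True)
    ca.fc1.weight.data = np.eye(3, dtype=np.float32)
    ca.fc2.weight.data = np.eye(3, dtype=np.float32)
    v = np.array([0.3, 1.2, 0.05], dtype=np.float32)
    x = np.broadcast_to(v[:, None, None], (3, 4, 4))
    out = single(ca(t(x))).ravel()
    np.testing.assert_allclose(out, oracles.sigmoid(2 * v), **TOL)


def test_channel_attention_matches_scalar_oracle(rng):
    ca = seed_params(ChannelAttention(2, reduction=1), 11)
    x = rng.normal(size=(2, 2, 2)).astype(np.float32)
    out = single(ca(t(x))).ravel()
    expect = oracles.channel_attention_oracle(
        x, ca.fc1.weight.data, ca.fc1.bias.data, ca.fc2.weight.data, ca.fc2.bias.data
    )
    np.testing.assert_allclose(out, expect, **TOL)


def test_spatial_attention_zero_kernel_gives_half():
    sa = SpatialAttention(bias=True)
    zero_convs(sa)
    out = sa(t(np.random.default_rng(0).normal(size=(3, 6, 6))))
    np.testing.assert_allclose(out.data, 0.5, **TOL)


def test_spatial_attention_matches_loop_conv_oracle(rng):
    sa = seed_params(SpatialAttention(), 5)
    x = rng.normal(size=(3, 8, 8)).astype(np.float32)
    out = single(sa(t(x)))[0]
    expect = oracles.spatial_attention_oracle(x, sa.conv.weight.data)
    np.testing.assert_allclose(out, expect, **TOL)
    assert (out > 0).all() and (out < 1).all()


def test_cbam_zero_input_and_shape(rng):
    cb = seed_params(CBAM(4, reduction=2), 7)
    assert np.all(cb(t(np.zeros((4, 6, 6)))).data == 0)
    out = cb(t(rng.normal(size=(4, 9, 5))))
    assert out.shape == (1, 4, 9, 5)


def test_cbam_matches_composition_oracle(rng):
    cb = seed_params(CBAM(4, reduction=2), 9)
    x = rng.normal(size=(4, 6, 6)).astype(np.float32)
    out = single(cb(t(x)))
    expect = oracles.cbam_oracle(
        x,
        (cb.ca.fc1.weight.data, None, cb.ca.fc2.weight.data, None),
        (cb.sa.conv.weight.data,),
    )
    np.testing.assert_allclose(out, expect, **TOL)


# -- split / shuffle --------------------------------------------------------

def test_channel_split_definition_and_inverse(rng):
    x = t(rng.normal(size=(4, 3, 3)))
    a, b = channel_split(x)
    np.testing.assert_array_equal(a.data, x.data[:, :2])
    np.testing.assert_array_equal(b.data, x.data[:, 2:])
    np.testing.assert_array_equal(concat([a, b], axis=1).data, x.data)
    a2, b2 = channel_split(t(rng.normal(size=(2, 3, 3))))
    assert a2.shape[1] == b2.shape[1] == 1
    with pytest.raises(ValueError, match="even"):
        channel_split(t(rng.normal(size=(3, 2, 2))))


def test_channel_shuffle_interleave_and_involution(rng):
    x = t(rng.normal(size=(4, 2, 2)))
    out = channel_shuffle(x, 2)
    np.testing.assert_array_equal(out.data[0], x.data[0][[0, 2, 1, 3]])
    twice = channel_shuffle(out, 2)
    np.testing.assert_array_equal(twice.data, x.data)  # groups=2, C=4: involution
    np.testing.assert_array_equal(channel_shuffle(x, 1).data, x.data)
    with pytest.raises(ValueError, match="divisible"):
        channel_shuffle(x, 3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 4), st.sampled_from([2, 3, 4]))
def test_channel_shuffle_is_a_permutation(depth_seed, groups):
    c = groups * depth_seed * 2
    x = np.random.default_rng(depth_seed * 7 + groups).normal(size=(1, c, 3, 3))
    x32 = x.astype(np.float32)
    out = channel_shuffle(Tensor(x32), groups)
    sums_in = np.sort(x32.sum(axis=(0, 2, 3), dtype=np.float64))
    sums_out = np.sort(out.data.sum(axis=(0, 2, 3), dtype=np.float64))
    np.testing.assert_array_equal(sums_in, sums_out)  # exact: values only move


# -- pyramid pooling ---------------------------------------------------------

def test_ppm_zero_branches_pass_through(rng):
    ppm = PyramidPooling(8, groups=4)
    identity_bns(zero_convs(ppm))
    x = rng.normal(size=(8, 7, 9)).astype(np.float32)
    out = single(ppm(t(x)))
    np.testing.assert_array_equal(out, x)


def test_ppm_shape_preserved_and_channel_constraint(rng):
    ppm = seed_params(PyramidPooling(8, groups=4), 2)
    identity_bns(ppm)
    assert ppm(t(rng.normal(size=(8, 12, 12)))).shape == (1, 8, 12, 12)
    with pytest.raises(ValueError, match="divisible by 4"):
        PyramidPooling(6)


def test_ppm_matches_stepwise_oracle(rng):
    ppm = seed_params(PyramidPooling(8, groups=4), 21)
    identity_bns(ppm)
    x = rng.normal(size=(8, 12, 12)).astype(np.float32)
    out = single(ppm(t(x)))
    expect = oracles.ppm_oracle(
        x,
        [c.weight.data for c in ppm.reduce.layers],
        ppm.proj.weight.data.reshape(8, 2, 1, 1),
        ppm.post.weight.data,
    )
    np.testing.assert_allclose(out, expect, rtol=2e-5, atol=1e-5)


# -- feature fusion ----------------------------------------------------------

def test_ffm_contract_zero_and_mismatch(rng):
    ffm = seed_params(FeatureFusion(4, 4, 4), 3)
    identity_bns(ffm)
    za = t(np.zeros((4, 4, 4)))
    zero_convs(ffm)
    assert np.all(ffm(za, za).data == 0)
    with pytest.raises(ValueError, match="spatial"):
        seed_params(ffm, 3)(t(np.zeros((4, 4, 4))), t(np.zeros((4, 6, 6))))


def test_ffm_matches_stepwise_oracle(rng):
    ffm = seed_params(FeatureFusion(4, 4, 4), 17)
    identity_bns(ffm)
    a = rng.normal(size=(4, 4, 4)).astype(np.float32)
    b = rng.normal(size=(4, 4, 4)).astype(np.float32)
    out = single(ffm(t(a), t(b)))
    conv = ffm.fuse.layers[0]
    expect = oracles.ffm_oracle(a, b, conv.weight.data, 4)
    np.testing.assert_allclose(out, expect, rtol=1e-5, atol=1e-5)
    assert out.shape == (4, 4, 4)


def test_context_block_zero_weights_pass_through(rng):
    cb = ContextBlock(8, 4)
    identity_bns(zero_convs(cb))
    x = rng.normal(size=(8, 5, 5)).astype(np.float32)
    np.testing.assert_array_equal(single(cb(t(x))), x)


# -- batch behaviour ---------------------------------------------------------

@pytest.mark.parametrize("factory", [
    lambda: Downsample(4, 8),
    lambda: CBAM(4, 2),
    lambda: PyramidPooling(4, groups=2),
    lambda: ContextBlock(4, 2),
])
def test_blocks_map_batches_elementwise(rng, factory):
    """Permuting samples in a batch permutes outputs identically."""
    block = seed_params(factory(), 31)
    identity_bns(block)
    x = rng.normal(size=(3, 4, 8, 8)).astype(np.float32)
    perm = [2, 0, 1]
    with no_grad():
        out = block(Tensor(x)).data
        out_perm = block(Tensor(x[perm])).data
    np.testing.assert_allclose(out[perm], out_perm, **TOL)
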