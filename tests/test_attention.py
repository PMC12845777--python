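"""Attention-zoo behaviour: kernel-size rule, pooling duality, gates,
shape preservation and hand-counted weight totals."""

import math

import numpy as np
import pytest

from gefay.attention import (GEFA, MLCA, SE, AttentionSpec, EcaKernelPolicy,
                             build_attention, eca_kernel_size, local_avg_pool,
                             local_unpool)
from gefay.autograd import Tensor
from gefay.nn import ChannelConv1d


# -- adaptive kernel size ---------------------------------------------------

def brute_force_k(c, gamma=2.0, b=2.0, min_k=3):
    v = math.log2(c) / gamma + b / gamma
    k = math.floor(v + 0.5)
    if k % 2 == 0:
        k += 1
    return max(k, min_k)


@pytest.mark.parametrize("c,expected", [(256, 5), (2, 3), (1, 3), (512, 7), (64, 5)])
def test_kernel_size_examples(c, expected):
    assert eca_kernel_size(c) == expected


def test_kernel_size_matches_brute_force_and_is_odd():
    for c in range(1, 4097):
        k = eca_kernel_size(c)
        assert k == brute_force_k(c)
        assert k % 2 == 1 and k >= 3


def test_kernel_size_rejects_bad_channels():
    with pytest.raises(ValueError):
        eca_kernel_size(0)


def test_kernel_policy_validation():
    with pytest.raises(ValueError):
        EcaKernelPolicy(gamma=0)
    with pytest.raises(ValueError):
        EcaKernelPolicy(min_k=4)


# -- local average pooling / de-pooling ------------------------------------

def loop_block_mean(x, p):
    """Explicit-loop oracle for the adaptive block mean."""
    n, c, h, w = x.shape
    out = np.zeros((n, c, p, p))
    for i in range(p):
        for j in range(p):
            r0, r1 = (i * h) // p, -((-(i + 1) * h) // p)
            c0, c1 = (j * w) // p, -((-(j + 1) * w) // p)
            out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
    return out


def test_local_avg_pool_constant_and_blocks():
    x = np.full((1, 2, 8, 8), 3.25, np.float32)
    assert np.allclose(local_avg_pool(Tensor(x), 3).data, 3.25)
    blocks = np.kron(np.array([[1.0, 3.0], [2.0, 4.0]]), np.ones((2, 2)))
    out = local_avg_pool(Tensor(blocks[None, None]), 2).data
    assert np.allclose(out[0, 0], [[1, 3], [2, 4]])


def test_local_avg_pool_matches_loop_oracle(rng):
    x = rng.normal(0, 1, (1, 1, 8, 8)).astype(np.float32)
    assert np.allclose(local_avg_pool(Tensor(x), 2).data,
                       loop_block_mean(x, 2), atol=1e-6)
    # global mean preserved when H, W are multiples of p
    assert np.isclose(local_avg_pool(Tensor(x), 2).data.mean(), x.mean(),
                      atol=1e-6)


def test_local_unpool_oracle_and_round_trip(rng):
    w = rng.normal(0, 1, (1, 3, 2, 2)).astype(np.float32)
    out = local_unpool(Tensor(w), 6, 6).data
    for y in range(6):
        for x_ in range(6):
            assert out[0, :, y, x_] == pytest.approx(w[0, :, (y * 2) // 6, (x_ * 2) // 6])
    # pool(unpool(w)) is the identity when the target is a multiple of p
    back = local_avg_pool(local_unpool(Tensor(w), 8, 8), 2).data
    assert np.allclose(back, w, atol=1e-6)
    # p = 1 broadcasts the single value
    one = local_unpool(Tensor(np.array([[[[2.5]]]], np.float32)), 4, 5).data
    assert np.allclose(one, 2.5)


def test_local_unpool_rejects_oversized_grid():
    with pytest.raises(ValueError):
        local_unpool(Tensor(np.zeros((1, 1, 4, 4), np.float32)), 3, 3)


# -- 1-D channel mixer ------------------------------------------------------

def test_channel_mixer_impulse_identity_and_param_count(rng):
    mixer = ChannelConv1d(3, rng=rng)
    mixer.weight.data = np.array([0, 1, 0], np.float32)  # centred unit impulse
    x = rng.normal(0, 1, (2, 5, 4)).astype(np.float32)
    assert np.allclose(mixer(Tensor(x)).data, x, atol=1e-6)
    assert mixer.num_parameters() == 3
    assert ChannelConv1d(7).num_parameters() == 7  # k weights, any C, m


def test_channel_mixer_matches_convolution_oracle():
    mixer = ChannelConv1d(3)
    mixer.weight.data = np.array([0.25, 0.5, 0.25], np.float32)
    ramp = np.arange(1.0, 5.0, dtype=np.float32).reshape(1, 4, 1)
    out = mixer(Tensor(ramp)).data[0, :, 0]
    expected = [np.dot([0.25, 0.5, 0.25], [0, 1, 2]),  # zero padded
                np.dot([0.25, 0.5, 0.25], [1, 2, 3]),
                np.dot([0.25, 0.5, 0.25], [2, 3, 4]),
                np.dot([0.25, 0.5, 0.25], [3, 4, 0])]
    assert np.allclose(out, expected, atol=1e-6)


def test_channel_mixer_rejects_even_kernel():
    with pytest.raises(ValueError):
        ChannelConv1d(4)


# -- plug-in contract across variants ---------------------------------------

ALL = ["se", "eca", "ca", "cbam", "mlca", "gefa"]


@pytest.mark.parametrize("variant", ALL)
def test_shape_preservation_and_gate_effect(variant, rng):
    c, h, w = 32, 20, 20
    mod = build_attention(variant, c, AttentionSpec(variant), rng=rng)
    x = rng.normal(0, 1, (2, c, h, w)).astype(np.float32)
    y = mod(Tensor(x))
    assert y.shape == x.shape
    assert np.isfinite(y.data).all()


@pytest.mark.parametrize("variant", ["se", "eca", "ca", "cbam", "mlca"])
def test_multiplicative_gates_shrink_magnitude(variant, rng):
    """Multiplicative attentions gate with weights in (0,1): |y| < |x|
    elementwise wherever x is nonzero."""
    c = 16
    mod = build_attention(variant, c, AttentionSpec(variant), rng=rng)
    x = rng.normal(0, 1, (1, c, 12, 12)).astype(np.float32) + 0.1
    y = mod(Tensor(x)).data
    assert (np.abs(y) < np.abs(x) + 1e-7).all()
    assert (np.abs(y) > 0).all()  # gate never reaches exactly 0


def test_gefa_gate_bounds_and_residual_identity(rng):
    spec = AttentionSpec("gefa", groups=8, group_width_factor=1.625)
    mod = GEFA(64, spec, rng=rng)
    x = rng.normal(0, 1, (2, 64, 10, 10)).astype(np.float32)
    y = mod(Tensor(x)).data
    # reconstruct the internal gate and enhanced features
    u = mod.bn2(mod.enhance2(mod.bn1(mod.enhance1(Tensor(x))).silu()))
    loc = mod.mixer(local_avg_pool(u, mod.p).reshape(2, 64, 25))
    loc = local_unpool(loc.reshape(2, 64, mod.p, mod.p), 10, 10)
    glo = mod.mixer_global(
        local_avg_pool(u, 1).reshape(2, 64, 1)).reshape(2, 64, 1, 1)
    a = ((loc + glo) * 0.5).sigmoid().data
    assert ((a > 0) & (a < 1)).all()
    assert np.allclose(y, x + a * u.data, atol=1e-5)
    # residual limits: the update is exactly gated by a
    assert np.allclose(y - x, a * u.data, atol=1e-5)


def test_gefa_validates_divisibility_and_grid(rng):
    with pytest.raises(ValueError):
        GEFA(30, AttentionSpec("gefa", groups=8), rng=rng)  # 30 % 8 != 0
    mod = GEFA(64, AttentionSpec("gefa", local_grid=5), rng=rng)
    with pytest.raises(ValueError):
        mod(Tensor(np.zeros((1, 64, 4, 4), np.float32)))  # H < p


# -- weight inventories vs hand counts --------------------------------------

@pytest.mark.parametrize("c,r,expected", [
    (64, 4, 2 * 64 * 16),       # printed configuration SE/4
    (128, 4, 2 * 128 * 32),
    (96, 16, 2 * 96 * 6),
])
def test_se_parameter_hand_count(c, r, expected, rng):
    assert SE(c, r, rng=rng).num_parameters() == expected


def test_eca_parameter_count_via_kernel_rule(rng):
    mod = build_attention("eca", 256, rng=rng)
    assert mod.num_parameters() == 5  # k(256) = 5 weights


@pytest.mark.parametrize("c,g,wf,k", [(64, 8, 1.625, 1), (128, 8, 1.625, 1),
                                      (64, 4, 0.5, 3)])
def test_gefa_parameter_hand_count(c, g, wf, k, rng):
    spec = AttentionSpec("gefa", groups=g, group_width_factor=wf, group_kernel=k)
    hid = int(wf * c)
    expected = (k * k * c * hid // g + 2 * hid   # grouped kxk conv + bn
                + hid * c // g + 2 * c           # grouped 1x1 conv + bn
                + eca_kernel_size(c))            # shared mixer
    assert GEFA(c, spec, rng=rng).num_parameters() == expected


def test_mlca_parameter_count_is_just_the_mixer(rng):
    assert MLCA(256, 5, rng=rng).num_parameters() == 5


def test_construction_determinism(rng):
    spec = AttentionSpec("gefa")
    a = build_attention("gefa", 64, spec, rng=np.random.default_rng(5))
    b = build_attention("gefa", 64, spec, rng=np.random.default_rng(5))
    x = rng.normal(0, 1, (1, 64, 8, 8)).astype(np.float32)
    names_a = dict(a.named_parameters())
    names_b = dict(b.named_parameters())
    assert names_a.keys() == names_b.keys()
    for k in names_a:
        assert np.array_equal(names_a[k].data, names_b[k].data)
    assert np.array_equal(a(Tensor(x)).data, b(Tensor(x)).data)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        AttentionSpec("swin")
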