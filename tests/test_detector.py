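"""Detector graph construction: hand-counted block sizes, depth/width
scaling rules, channel bookkeeping and forward-pass contracts."""

import numpy as np
import pytest

from gefay.attention import AttentionSpec
from gefay.autograd import Tensor
from gefay.blocks import AttentionC3, C3, ConvBlock, SPPF
from gefay.model import ModelSpec, build_model, make_divisible


@pytest.mark.parametrize("c1,c2,k,expected", [
    (3, 32, 6, 3 * 32 * 36 + 64),     # stem: 3,520
    (64, 64, 1, 64 * 64 + 128),       # 1x1: 4,224
    (16, 32, 3, 16 * 32 * 9 + 64),
])
def test_conv_block_parameter_hand_count(c1, c2, k, expected, rng):
    assert ConvBlock(c1, c2, k, rng=rng).num_parameters() == expected


def test_conv_block_preserves_size_at_stride_1(rng):
    blk = ConvBlock(4, 8, 1, 1, rng=rng)
    out = blk(Tensor(np.zeros((1, 4, 9, 9), np.float32)))
    assert out.shape == (1, 8, 9, 9)


def c3_hand_count(c1, c2, n):
    c_ = c2 // 2
    conv = lambda a, b, k: k * k * a * b + 2 * b
    total = conv(c1, c_, 1) * 2 + conv(2 * c_, c2, 1)
    total += n * (conv(c_, c_, 1) + conv(c_, c_, 3))
    return total


def test_c3_parameter_closed_form(rng):
    assert C3(64, 64, 1, rng=rng).num_parameters() == c3_hand_count(64, 64, 1)
    assert C3(32, 64, 2, rng=rng).num_parameters() == c3_hand_count(32, 64, 2)


def test_c3_rejects_odd_width(rng):
    with pytest.raises(ValueError):
        C3(16, 15, rng=rng)


@pytest.mark.parametrize("n_base,depth,expected", [
    (3, 0.33, 1), (6, 0.33, 2), (9, 0.33, 3), (3, 1.0, 3), (1, 0.33, 1),
])
def test_depth_scaling_rule(n_base, depth, expected):
    assert max(1, round(n_base * depth)) == expected


def test_attention_c3_none_equals_plain_c3(rng):
    plain = C3(64, 64, 1, rng=np.random.default_rng(3))
    wrapped = AttentionC3(64, 64, 1, spec=AttentionSpec("none"),
                          rng=np.random.default_rng(3))
    assert wrapped.num_parameters() == plain.num_parameters()
    x = Tensor(np.random.default_rng(0).normal(0, 1, (1, 64, 8, 8)).astype(np.float32))
    assert np.array_equal(plain(x).data, wrapped(x).data)


def test_attention_c3_se_adds_exact_delta(rng):
    base = AttentionC3(64, 64, 1, spec=AttentionSpec("none"), rng=rng)
    se = AttentionC3(64, 64, 1, spec=AttentionSpec("se", reduction=4), rng=rng)
    assert se.num_parameters() - base.num_parameters() == 2048
    x = Tensor(np.zeros((1, 64, 8, 8), np.float32))
    assert se(x).shape == base(x).shape


def test_sppf_output_shape(rng):
    sppf = SPPF(64, 64, 5, rng=rng)
    out = sppf(Tensor(np.random.default_rng(1).normal(0, 1, (1, 64, 6, 6))
                      .astype(np.float32)))
    assert out.shape == (1, 64, 6, 6)


# -- whole-model properties -------------------------------------------------

def head_hand_count(nc, width=0.50):
    chans = [make_divisible(c * width) for c in (256, 512, 1024)]
    return sum(c * 3 * (nc + 5) + 3 * (nc + 5) for c in chans)


def test_head_parameter_hand_counts():
    assert head_hand_count(80) == 229_245
    assert head_hand_count(20) == 67_425


def test_nc_only_touches_the_head():
    base = {nc: build_model(ModelSpec(nc=nc, attention=AttentionSpec("none")))
            .num_parameters() for nc in (12, 20, 80)}
    # (128 + 256 + 512 + 3) * 3 per class at width 0.50
    assert base[80] - base[20] == 2697 * 60
    assert base[20] - base[12] == 2697 * 8


def test_layer_records_are_reproducible_and_consistent(tiny_model_spec):
    a = build_model(tiny_model_spec, seed=4)
    b = build_model(tiny_model_spec, seed=4)
    assert a.table() == b.table()
    recs = {r.index: r for r in a.layer_records}
    for r in a.layer_records:
        if r.kind == "concat":
            assert r.out_channels == sum(recs[f].out_channels for f in r.from_)
    assert sum(r.params for r in a.layer_records) == a.num_parameters()


def test_forward_strides_and_batch_axis(tiny_model_spec):
    model = build_model(tiny_model_spec)
    x = np.random.default_rng(0).random((2, 3, 160, 160)).astype(np.float32)
    outs = model.forward(Tensor(x))
    assert [o.shape[2] for o in outs] == [20, 10, 5]  # strides 8/16/32
    assert all(o.shape[0] == 2 and o.shape[1] == 3 and o.shape[4] == 9
               for o in outs)


def test_forward_rejects_indivisible_input(tiny_model_spec):
    model = build_model(tiny_model_spec)
    with pytest.raises(ValueError):
        model.forward(np.zeros((1, 3, 100, 100), np.float32))


def test_grid_sizes_scale_with_input(tiny_model_spec):
    model = build_model(tiny_model_spec)
    outs = model.forward(np.zeros((1, 3, 320, 320), np.float32))
    assert [o.shape[2] for o in outs] == [40, 20, 10]


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ModelSpec(nc=0)
    with pytest.raises(ValueError):
        ModelSpec(attention_placement=("P9",))
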