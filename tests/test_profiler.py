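"""Profiler correctness: truncation convention, FLOP hand counts,
monotonicity, nc-independence of attention deltas, and the GEFA
calibration contract."""

import numpy as np
import pytest

from gefay.attention import AttentionSpec
from gefay.model import ModelSpec, build_model
from gefay.nn import Conv2d
from gefay.profiler import (CalibrationError, FlopConvention, calibrate_gefa,
                            count_flops, count_parameters, gefa_delta,
                            parse_table_report, profile, table_report,
                            truncate_mega, _module_counts)

BASE = ModelSpec(nc=20, attention=AttentionSpec("none"))


@pytest.mark.parametrize("n,expected", [
    (7_235_389, 7.23), (7_073_569, 7.07), (7_399_999, 7.39), (999_999, 0.99),
])
def test_truncation_convention(n, expected):
    assert truncate_mega(n) == expected


def test_single_conv_flop_hand_count(rng):
    conv = Conv2d(64, 64, 1, rng=rng)
    counts, oh, ow = _module_counts(conv, 80, 80)
    assert (oh, ow) == (80, 80)
    assert counts.conv_macs == 64 * 64 * 6400  # 26.2 MMACs
    conv_b = Conv2d(64, 64, 1, bias=True, rng=rng)
    counts_b, _, _ = _module_counts(conv_b, 80, 80)
    assert counts_b.bias_adds == 64 * 6400
    # a 3x3 stride-2 conv halves the grid
    counts3, oh3, _ = _module_counts(Conv2d(16, 32, 3, 2, rng=rng), 40, 40)
    assert oh3 == 20 and counts3.conv_macs == 9 * 16 * 32 * 400


def test_params_match_independent_enumeration():
    """Report totals equal a from-scratch walk over the weight arrays."""
    model = build_model(BASE)
    rep = count_parameters(model)
    enumerated = sum(int(np.prod(p.data.shape)) for p in model.parameters())
    assert rep.total_params == enumerated
    assert rep.total_params == sum(p for _, p, _ in rep.breakdown)
    assert rep.params_mega == truncate_mega(enumerated)


def test_flops_scale_quadratically_with_input():
    model = build_model(BASE)
    f320 = count_flops(model, 320).flops_total
    f640 = count_flops(model, 640).flops_total
    assert f640 == pytest.approx(4 * f320, rel=1e-3)


def test_attention_never_decreases_complexity():
    reports = {}
    for variant in ("none", "eca", "se", "mlca", "gefa", "cbam", "ca"):
        model = build_model(BASE.with_(attention=AttentionSpec(variant)))
        reports[variant] = profile(model, 640)
    for variant, rep in reports.items():
        assert rep.total_params >= reports["none"].total_params
        assert rep.flops_total >= reports["none"].flops_total


def test_attention_delta_independent_of_class_count():
    for variant in ("se", "gefa"):
        deltas = set()
        for nc in (12, 20, 80):
            none = build_model(ModelSpec(nc=nc, attention=AttentionSpec("none")))
            att = build_model(ModelSpec(nc=nc, attention=AttentionSpec(variant)))
            deltas.add(att.num_parameters() - none.num_parameters())
        assert len(deltas) == 1


def test_gefa_closed_form_delta_matches_built_model():
    spec = AttentionSpec("gefa")
    delta = gefa_delta(BASE, spec, BASE.attention_placement)
    none = build_model(BASE).num_parameters()
    gefa = build_model(BASE.with_(attention=spec)).num_parameters()
    assert gefa - none == delta


def test_calibration_returns_configuration_matching_both_cells():
    res = calibrate_gefa(ModelSpec(nc=12))
    assert truncate_mega(res.params_nc20) == 7.39
    assert truncate_mega(res.params_nc80) == 7.55
    # the returned spec actually builds to those counts
    built = build_model(ModelSpec(nc=20, attention=res.spec,
                                  attention_placement=res.placement))
    assert built.num_parameters() == res.params_nc20


def test_calibration_rejects_infeasible_search_space():
    with pytest.raises(CalibrationError) as exc:
        calibrate_gefa(ModelSpec(nc=12), search_space={
            "group_width_factor": (1.0,), "group_kernel": (3,)})
    assert exc.value.near_misses  # diagnostic, never silent


def test_variant_none_delta_is_zero_hence_outside_window():
    spec = AttentionSpec("gefa")
    assert gefa_delta(BASE, spec, ()) == 0  # no slots -> no delta


def test_table_report_round_trip():
    base = ModelSpec(nc=20)
    specs = [AttentionSpec("none"), AttentionSpec("se"), AttentionSpec("eca"),
             AttentionSpec("gefa")]
    text = table_report(base, specs, 640)
    rows = parse_table_report(text)
    assert [r[0] for r in rows] == ["NONE", "SE/4", "ECA", "GEFA (5 x 5)"]
    assert rows[0][2] == 7.07  # baseline cell
    assert all(r[2] >= rows[0][2] for r in rows)  # params non-decreasing
    assert parse_table_report(text) == rows


def test_flop_convention_is_explicit_and_additive():
    model = build_model(BASE)
    free = count_flops(model, 640, FlopConvention(2, 0, 0, 0, 0)).flops_total
    full = count_flops(model, 640).flops_total
    assert full > free  # the calibrated convention adds elementwise terms
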