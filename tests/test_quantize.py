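"""Quantization parameters, calibration, conversion and export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tinybeat.cnn import Architecture, build_model
from tinybeat.quantize import (
    QuantizationError,
    QuantParams,
    calibrate,
    choose_qparams,
    convert,
    dequantize,
    deserialize,
    export_c_header,
    export_portable,
    float_weight_payload_bytes,
    fold_batchnorm,
    load_portable,
    quantize_multiplier,
    quantize_value,
    representative_subsample,
    serialize,
    weight_payload_bytes,
)

TINY_ARCH = Architecture(
    input_length=20, conv_filters=(4,), conv_kernels=(3,), pool_after=(0,),
    dense_units=(6,), dropout_rate=0.0,
)


def _tiny_quant(seed=0, n_rep=16):
    model = build_model(TINY_ARCH, seed=seed)
    rep = np.random.default_rng(seed).random((n_rep, 20))
    qm = convert(model, calibrate(model, rep))
    return model, qm


def test_weight_qparams_symmetric():
    qp = choose_qparams((-0.5, 0.25), "weights")
    assert qp.scale == pytest.approx(0.5 / 127)
    assert qp.zero_point == 0


def test_activation_qparams_asymmetric():
    qp = choose_qparams((0.0, 2.55), "activations")
    assert qp.scale == pytest.approx(0.01)
    assert qp.zero_point == -128


def test_activation_qparams_symmetric_range_zero_zp():
    qp = choose_qparams((-1.0, 1.0), "activations")
    assert qp.zero_point == 0


@pytest.mark.parametrize("x,scale,zp,expected", [
    (0.0, 0.5, 0, 0),
    (1.0, 0.5, 0, 2),
    (100.0, 0.5, 0, 127),   # saturation
    (-100.0, 0.5, 0, -128),
    (0.75, 0.5, 0, 2),      # 1.5 rounds away from zero
    (-0.75, 0.5, 0, -2),
])
def test_quantize_value_examples(x, scale, zp, expected):
    assert int(quantize_value(x, QuantParams(scale, zp))) == expected


def test_dequantize_round_trip_within_half_scale(rng):
    qp = choose_qparams((-0.3, 0.3), "weights")
    w = rng.uniform(-0.3, 0.3, 100)
    back = dequantize(quantize_value(w, qp), qp)
    assert np.abs(back - w).max() <= qp.scale / 2 + 1e-12


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-8, max_value=1e4))
def test_quantize_multiplier_accuracy(M):
    m0, n = quantize_multiplier(M)
    assert (1 << 30) <= m0 < (1 << 31)
    approx = m0 * 2.0 ** (-31 - n)
    assert abs(approx - M) / M < 2 ** -24


def test_calibrate_widens_to_contain_zero():
    model = build_model(TINY_ARCH, seed=1)
    ranges = calibrate(model, np.zeros((4, 20)))
    for lo, hi in ranges:
        assert lo <= 0.0 <= hi and hi > lo


def test_calibrate_ranges_monotone_in_data():
    model = build_model(TINY_ARCH, seed=1)
    rep = np.random.default_rng(0).random((20, 20))
    small = calibrate(model, rep[:5])
    large = calibrate(model, rep)
    for (lo_s, hi_s), (lo_l, hi_l) in zip(small, large):
        assert lo_l <= lo_s and hi_l >= hi_s


def test_calibrate_empty_rejected():
    with pytest.raises(QuantizationError):
        calibrate(build_model(TINY_ARCH, seed=0), np.zeros((0, 20)))


def test_representative_subsample_seeded(train_dataset):
    a = representative_subsample(train_dataset, 200, seed=2)
    b = representative_subsample(train_dataset, 200, seed=2)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (200, 250)


def test_fold_batchnorm_preserves_outputs(rng):
    arch = Architecture(
        input_length=30, conv_filters=(4, 6), conv_kernels=(3, 3), pool_after=(0,),
        dense_units=(5,), batch_norm_after_conv=True, dropout_rate=0.0,
    )
    model = build_model(arch, seed=4)
    # Give BN non-trivial statistics before folding.
    for layer in model.layers:
        if layer.kind == "batchnorm":
            layer.running_mean[...] = rng.standard_normal(layer.running_mean.size) * 0.1
            layer.running_var[...] = 0.5 + rng.random(layer.running_var.size)
            layer.gamma[...] = 0.8 + 0.4 * rng.random(layer.gamma.size)
            layer.beta[...] = rng.standard_normal(layer.beta.size) * 0.05
    folded = fold_batchnorm(model)
    X = rng.random((5, 30))
    np.testing.assert_allclose(
        model.forward(X, training=False), folded.forward(X, training=False),
        rtol=1e-9, atol=1e-9,
    )


def test_int8_payload_exactly_quarter_of_float32():
    model, qm = _tiny_quant()
    assert weight_payload_bytes(qm) / float_weight_payload_bytes(model) == 0.25


def test_bias_scale_is_input_times_weight_scale():
    _, qm = _tiny_quant()
    for op in qm.ops:
        if op.w is not None:
            # requant multiplier encodes (s_in * s_w) / s_out
            M = op.in_qp.scale * op.w_qp.scale / op.out_qp.scale
            approx = op.m0 * 2.0 ** (-31 - op.n)
            assert abs(approx - M) / M < 2 ** -24


def test_convert_missing_ranges_rejected():
    model = build_model(TINY_ARCH, seed=0)
    with pytest.raises(QuantizationError):
        convert(model, [(-1.0, 1.0)] * 2)


def test_stored_weights_within_int8_domain():
    _, qm = _tiny_quant()
    for op in qm.ops:
        if op.w is not None:
            assert op.w.dtype == np.int8
            assert op.w.min() >= -128 and op.w.max() <= 127


def test_portable_round_trip_bit_identical(tmp_path):
    _, qm = _tiny_quant()
    path = tmp_path / "m.tb"
    export_portable(qm, path)
    back = load_portable(path)
    assert serialize(back) == serialize(qm) == path.read_bytes()


def test_deserialize_rejects_garbage():
    with pytest.raises(QuantizationError):
        deserialize(b"NOPE" + b"\x00" * 20)


def test_c_header_structure():
    _, qm = _tiny_quant()
    header = export_c_header(qm)
    raw = serialize(qm)
    assert header.count("{") == header.count("}") == 1
    assert f"unsigned int model_len = {len(raw)};" in header
    body = header.split("{", 1)[1].rsplit("}", 1)[0]
    parsed = bytes(int(tok, 16) for tok in body.replace("\n", " ").split(",") if tok.strip())
    assert parsed == raw
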