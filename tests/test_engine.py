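"""Integer-only inference: kernels vs float oracle, classify, footprint."""

import numpy as np
import pytest

from tinybeat.cnn import Architecture, build_model
from tinybeat.containers import BeatLabel
from tinybeat.engine import (
    Int8Tensor,
    classify,
    conv1d_int8,
    dense_int8,
    footprint,
    maxpool_int8,
    predict_int8,
    requantize,
    run_int8,
)
from tinybeat.quantize import (
    QuantOp,
    QuantParams,
    calibrate,
    choose_qparams,
    convert,
    quantize_multiplier,
    quantize_value,
    serialize,
)


@pytest.mark.parametrize("acc,M,expected", [
    (128, 0.25, 32),
    (3, 0.5, 2),      # 1.5 rounds away from zero
    (-3, 0.5, -2),
    (0, 0.37, 0),
])
def test_requantize_examples(acc, M, expected):
    m0, n = quantize_multiplier(M)
    assert requantize(acc, m0, n) == expected


def test_requantize_rejects_bad_m0():
    with pytest.raises(ValueError):
        requantize(10, 123, 0)


def _random_quant_dense(n_in, n_out, seed):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.4, 0.4, (n_in, n_out))
    b = rng.uniform(-0.2, 0.2, n_out)
    in_qp = choose_qparams((0.0, 1.0), "activations")
    w_qp = choose_qparams((w.min(), w.max()), "weights")
    x = rng.random((3, n_in))
    xq = quantize_value(x, in_qp)
    # float oracle on dequantized tensors
    wq = quantize_value(w, w_qp)
    bias_scale = in_qp.scale * w_qp.scale
    bq = np.round(b / bias_scale).astype(np.int32)
    acc_f = ((xq.astype(float) - in_qp.zero_point) * in_qp.scale) @ (
        wq.astype(float) * w_qp.scale
    ) + bq * bias_scale
    out_qp = choose_qparams((float(acc_f.min()), float(acc_f.max())), "activations")
    m0, n = quantize_multiplier(bias_scale / out_qp.scale)
    op = QuantOp(kind="dense", relu=False, w=wq, b=bq, w_qp=w_qp,
                 in_qp=in_qp, out_qp=out_qp, m0=m0, n=n)
    return op, Int8Tensor(xq, in_qp), acc_f


@pytest.mark.parametrize("seed", [5, 6, 7])
def test_dense_int8_matches_float_oracle(seed):
    op, x, acc_f = _random_quant_dense(8, 4, seed)
    out = dense_int8(x, op)
    np.testing.assert_allclose(out.dequantize(), acc_f, atol=op.out_qp.scale)


def test_dense_zero_weights_outputs_bias():
    op, x, _ = _random_quant_dense(8, 4, 9)
    op.w = np.zeros_like(op.w)
    bias_scale = op.in_qp.scale * op.w_qp.scale
    bias_real = op.b * bias_scale
    # output range must cover the biases now that the weights are zero
    out_qp = choose_qparams(
        (min(float(bias_real.min()), 0.0), max(float(bias_real.max()), 1e-3)),
        "activations",
    )
    op.out_qp = out_qp
    op.m0, op.n = quantize_multiplier(bias_scale / out_qp.scale)
    out = dense_int8(x, op)
    np.testing.assert_allclose(
        out.dequantize(), np.broadcast_to(bias_real, out.values.shape),
        atol=out_qp.scale,
    )


def test_dense_permutation_symmetry():
    op, x, _ = _random_quant_dense(8, 4, 11)
    perm = np.random.default_rng(0).permutation(8)
    op2 = QuantOp(kind="dense", relu=op.relu, w=op.w[perm], b=op.b, w_qp=op.w_qp,
                  in_qp=op.in_qp, out_qp=op.out_qp, m0=op.m0, n=op.n)
    x2 = Int8Tensor(x.values[:, perm], x.qparams)
    np.testing.assert_array_equal(dense_int8(x, op).values, dense_int8(x2, op2).values)


def test_dense_qparams_mismatch_rejected():
    op, x, _ = _random_quant_dense(8, 4, 13)
    bad = Int8Tensor(x.values, QuantParams(x.qparams.scale * 2, x.qparams.zero_point))
    with pytest.raises(ValueError):
        dense_int8(bad, op)


def _random_quant_conv(length, c_in, c_out, seed, relu=False):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-0.4, 0.4, (3, c_in, c_out))
    b = rng.uniform(-0.1, 0.1, c_out)
    in_qp = choose_qparams((0.0, 1.0), "activations")
    w_qp = choose_qparams((w.min(), w.max()), "weights")
    x = rng.random((2, length, c_in))
    xq = quantize_value(x, in_qp)
    wq = quantize_value(w, w_qp)
    bias_scale = in_qp.scale * w_qp.scale
    bq = np.round(b / bias_scale).astype(np.int32)
    xd = (xq.astype(float) - in_qp.zero_point) * in_qp.scale
    wd = wq.astype(float) * w_qp.scale
    cols = np.lib.stride_tricks.sliding_window_view(xd, 3, axis=1)
    cols = cols.transpose(0, 1, 3, 2).reshape(2, -1, 3 * c_in)
    acc_f = cols @ wd.reshape(3 * c_in, c_out) + bq * bias_scale
    if relu:
        acc_f = np.maximum(acc_f, 0.0)
    out_qp = choose_qparams((min(float(acc_f.min()), 0.0), max(float(acc_f.max()), 1e-3)),
                            "activations")
    m0, n = quantize_multiplier(bias_scale / out_qp.scale)
    op = QuantOp(kind="conv", relu=relu, w=wq, b=bq, w_qp=w_qp,
                 in_qp=in_qp, out_qp=out_qp, m0=m0, n=n)
    return op, Int8Tensor(xq, in_qp), acc_f


@pytest.mark.parametrize("seed", [3, 4])
def test_conv_int8_matches_float_oracle(seed):
    op, x, acc_f = _random_quant_conv(12, 1, 2, seed)
    out = conv1d_int8(x, op)
    np.testing.assert_allclose(out.dequantize(), acc_f, atol=op.out_qp.scale)


def test_conv_identity_kernel_propagates_input(rng):
    # Single-tap-equivalent kernel dequantizing to 1 at the centre position.
    in_qp = choose_qparams((0.0, 1.0), "activations")
    w_qp = QuantParams(1 / 127, 0)
    w = np.zeros((3, 1, 1), dtype=np.int8)
    w[1, 0, 0] = 127  # dequantizes to exactly 1.0
    out_qp = in_qp
    m0, n = quantize_multiplier(in_qp.scale * w_qp.scale / out_qp.scale)
    op = QuantOp(kind="conv", relu=False, w=w, b=np.zeros(1, dtype=np.int32),
                 w_qp=w_qp, in_qp=in_qp, out_qp=out_qp, m0=m0, n=n)
    x = rng.random((1, 10, 1))
    xq = quantize_value(x, in_qp)
    out = conv1d_int8(Int8Tensor(xq, in_qp), op)
    ref = (xq[:, 1:-1, :].astype(float) - in_qp.zero_point) * in_qp.scale
    np.testing.assert_allclose(out.dequantize(), ref, atol=out_qp.scale)


def test_conv_relu_clamps_negative_preactivation():
    op, x, _ = _random_quant_conv(12, 1, 2, 8, relu=True)
    op.b = np.full_like(op.b, -(10 ** 6))  # force all-negative accumulators
    out = conv1d_int8(x, op)
    assert (out.values == op.out_qp.zero_point).all()


def test_maxpool_examples():
    qp = QuantParams(0.1, 0)
    x = Int8Tensor(np.array([[1, 5, 3, 2]], dtype=np.int8).reshape(1, 4, 1), qp)
    out = maxpool_int8(x, 2)
    np.testing.assert_array_equal(out.values.ravel(), [5, 3])
    assert out.qparams == qp
    const = Int8Tensor(np.full((1, 6, 2), 7, dtype=np.int8), qp)
    assert (maxpool_int8(const).values == 7).all()
    assert maxpool_int8(Int8Tensor(np.zeros((1, 9, 1), dtype=np.int8), qp)).values.shape[1] == 4


def _tiny_qmodel(seed=0):
    arch = Architecture(input_length=20, conv_filters=(4,), conv_kernels=(3,),
                        pool_after=(0,), dense_units=(6,), dropout_rate=0.0)
    model = build_model(arch, seed=seed)
    rep = np.random.default_rng(seed).random((16, 20))
    return model, convert(model, calibrate(model, rep))


def test_classify_deterministic_and_simplex(rng):
    _, qm = _tiny_qmodel()
    seg = rng.random(20)
    l1, p1 = classify(qm, seg, probabilities=True)
    l2, p2 = classify(qm, seg, probabilities=True)
    assert l1 == l2 and isinstance(l1, BeatLabel)
    np.testing.assert_array_equal(p1, p2)
    assert p1.sum() == pytest.approx(1.0)


def test_classify_wrong_length_rejected(rng):
    _, qm = _tiny_qmodel()
    with pytest.raises(ValueError):
        classify(qm, rng.random(19))


def test_label_path_is_integer_only(rng):
    _, qm = _tiny_qmodel()
    trace: list = []
    run_int8(qm, rng.random((3, 20)), trace=trace)
    assert len(trace) == len(qm.ops) + 1
    for arr in trace:
        assert np.issubdtype(arr.dtype, np.integer), arr.dtype


@pytest.mark.parametrize("seed", range(20))
def test_randomized_layers_within_accumulated_bound(seed):
    # Whole tiny graphs: dequantized int8 output within one output scale
    # of the float oracle run on dequantized tensors, layer by layer.
    op, x, acc_f = _random_quant_dense(32, 16, 100 + seed)
    out = dense_int8(x, op)
    assert np.abs(out.dequantize() - acc_f).max() <= op.out_qp.scale * (1 + 1e-9)


def test_footprint_flash_equals_payload():
    _, qm = _tiny_qmodel()
    fp = footprint(qm)
    assert fp.flash_bytes == len(serialize(qm))


def test_footprint_sram_lower_bound():
    _, qm = _tiny_qmodel()
    fp = footprint(qm)
    largest = max(max(r["in_bytes"], r["out_bytes"]) for r in fp.per_layer)
    assert fp.sram_bytes >= largest


def test_footprint_conv_buffer_scales_with_filters():
    def conv1_out_bytes(n_filters):
        arch = Architecture(input_length=20, conv_filters=(n_filters,), conv_kernels=(3,),
                            pool_after=(0,), dense_units=(6,), dropout_rate=0.0)
        model = build_model(arch, seed=0)
        rep = np.random.default_rng(0).random((8, 20))
        qm = convert(model, calibrate(model, rep))
        fp = footprint(qm)
        return next(r["out_bytes"] for r in fp.per_layer if r["op"] == "conv")

    assert conv1_out_bytes(8) == 2 * conv1_out_bytes(4)


def test_predict_int8_batch_labels(train_dataset, quant_model):
    labels, probs = predict_int8(quant_model, train_dataset.X[:20], probabilities=True)
    assert len(labels) == 20
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
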