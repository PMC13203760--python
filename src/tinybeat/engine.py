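"""Integer-only inference engine and memory-footprint accounting.

Executes a :class:`~tinybeat.quantize.QuantModel` the way a
microcontroller without a floating-point unit would: int8 tensors, int32
accumulators, fixed-point requantization.  For a conv or dense layer

    acc   = sum((q_in - zp_in) * q_w) + bias            (int32)
    q_out = clamp(requantize(acc, m0, n) + zp_out, -128, 127)

with ReLU fused as a floor clamp at ``zp_out``.  Requantization computes
``round(acc * m0 * 2^-31 * 2^-n)`` (round half away from zero) using the
64-bit high word of the product, as integer multipliers do in hardware;
the accumulators themselves are int32.

Classification uses integer argmax over the final int8 logits — softmax
is monotone, so probabilities are needed only for display, where they
are computed by dequantizing the logits (a floating-point step flagged
as such).

Footprint accounting assumes a two-buffer ping-pong schedule: at any op
the live SRAM is the input buffer + output buffer (int8) plus one int32
accumulator row; Flash is the serialized model payload.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BeatLabel, CLASS_ALPHABET
from .quantize import QuantModel, QuantOp, QuantParams, serialize


@dataclass
class Int8Tensor:
    """An int8 array with its quantization parameters."""

    values: np.ndarray
    qparams: QuantParams

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != np.int8:
            raise TypeError(f"Int8Tensor requires int8 values, got {self.values.dtype}")

    def dequantize(self) -> np.ndarray:
        return (self.values.astype(np.float64) - self.qparams.zero_point) * self.qparams.scale


@dataclass
class MemoryFootprint:
    """Flash (model payload) and peak SRAM (activation + scratch) bytes."""

    flash_bytes: int
    sram_bytes: int
    per_layer: list[dict]


def requantize(acc, m0: int, n: int):
    """Scale an int32 accumulator by ``m0 * 2^-31 * 2^-n`` in integer math.

    Rounding is half away from zero.  Accepts scalars or arrays; the
    64-bit product is internal (the accumulator stays int32).
    """
    if not (1 << 30) <= m0 < (1 << 31):
        raise ValueError(f"m0 must be in [2^30, 2^31), got {m0}")
    acc_arr = np.asarray(acc, dtype=np.int64)
    total_shift = 31 + n
    prod = acc_arr * np.int64(m0)
    if total_shift <= 0:
        out = prod << np.int64(-total_shift)
    else:
        rounding = np.int64(1) << np.int64(total_shift - 1)
        out = np.where(
            prod >= 0,
            (prod + rounding) >> np.int64(total_shift),
            -((-prod + rounding) >> np.int64(total_shift)),
        )
    out = np.clip(out, -(2 ** 31), 2 ** 31 - 1)
    return int(out) if np.isscalar(acc) else out.astype(np.int64)


def _finish(acc: np.ndarray, op: QuantOp) -> np.ndarray:
    """Requantize int32 accumulators to the int8 output domain."""
    q = requantize(acc, op.m0, op.n) + op.out_qp.zero_point
    lo = op.out_qp.zero_point if op.relu else -128
    return np.clip(q, lo, 127).astype(np.int8)


def conv1d_int8(inp: Int8Tensor, op: QuantOp) -> Int8Tensor:
    """Valid int8 convolution, stride 1, ReLU fused as clamp at zp_out.

    Input is (L, C) or (B, L, C) int8; weights are (k, C, F).
    """
    if op.kind != "conv":
        raise ValueError(f"op kind {op.kind!r} is not conv")
    if inp.qparams != op.in_qp:
        raise ValueError("input quantization parameters do not match the layer contract")
    x = inp.values
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    k, C, F = op.w.shape
    centred = x.astype(np.int32) - np.int32(op.in_qp.zero_point)
    cols = np.lib.stride_tricks.sliding_window_view(centred, k, axis=1)
    cols = cols.transpose(0, 1, 3, 2).reshape(x.shape[0], -1, k * C)
    acc = cols @ op.w.reshape(k * C, F).astype(np.int32) + op.b
    out = _finish(acc, op)
    return Int8Tensor(out[0] if squeeze else out, op.out_qp)


def maxpool_int8(inp: Int8Tensor, pool: int = 2) -> Int8Tensor:
    """Elementwise max over non-overlapping windows; qparams unchanged."""
    x = inp.values
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    B, L, C = x.shape
    if L < pool:
        raise ValueError(f"temporal length {L} < pool {pool}")
    lout = L // pool
    out = x[:, : lout * pool, :].reshape(B, lout, pool, C).max(axis=2)
    return Int8Tensor(out[0] if squeeze else out, inp.qparams)


def dense_int8(inp: Int8Tensor, op: QuantOp) -> Int8Tensor:
    """Fully connected int8 layer; same arithmetic contract as conv."""
    if op.kind != "dense":
        raise ValueError(f"op kind {op.kind!r} is not dense")
    if inp.qparams != op.in_qp:
        raise ValueError("input quantization parameters do not match the layer contract")
    x = inp.values
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None]
    centred = x.astype(np.int32) - np.int32(op.in_qp.zero_point)
    acc = centred @ op.w.astype(np.int32) + op.b
    out = _finish(acc, op)
    return Int8Tensor(out[0] if squeeze else out, op.out_qp)


def run_int8(qm: QuantModel, segments: np.ndarray, trace: list | None = None) -> Int8Tensor:
    """Run the integer graph on normalised segments; returns int8 logits.

    ``segments`` is (B, 250) real values in [0, 1]; the only non-integer
    step is quantizing the input with the model's input parameters.
    When ``trace`` is a list, every intermediate tensor is appended to it
    (used to audit that the label path is integer-only).
    """
    from .quantize import quantize_value

    segments = np.asarray(segments, dtype=np.float64)
    if segments.ndim == 1:
        segments = segments[None, :]
    if segments.shape[1] != qm.input_length:
        raise ValueError(
            f"expected segments of length {qm.input_length}, got {segments.shape[1]}"
        )
    x = Int8Tensor(quantize_value(segments, qm.input_qp)[:, :, None], qm.input_qp)
    if trace is not None:
        trace.append(x.values)
    for op in qm.ops:
        if op.kind == "conv":
            x = conv1d_int8(x, op)
        elif op.kind == "maxpool":
            x = maxpool_int8(x, op.pool)
        elif op.kind == "dense":
            x = dense_int8(x, op)
        elif op.kind == "flatten":
            x = Int8Tensor(x.values.reshape(x.values.shape[0], -1), x.qparams)
        else:  # pragma: no cover
            raise ValueError(f"unknown op kind {op.kind!r}")
        if trace is not None:
            trace.append(x.values)
    return x


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def predict_int8(qm: QuantModel, segments: np.ndarray, probabilities: bool = False):
    """Batch classification; returns labels and optionally display probabilities."""
    logits = run_int8(qm, segments)
    pred = logits.values.argmax(axis=-1)
    labels = [CLASS_ALPHABET[p] for p in pred]
    if not probabilities:
        return labels, None
    # Display path only: dequantize + softmax uses floating point.
    return labels, _softmax(logits.dequantize())


def classify(
    qm: QuantModel, segment: np.ndarray, probabilities: bool = False
) -> tuple[BeatLabel, np.ndarray | None]:
    """Classify one 250-sample normalised segment on the integer path."""
    labels, probs = predict_int8(qm, np.asarray(segment, dtype=np.float64)[None, :], probabilities)
    return labels[0], (probs[0] if probs is not None else None)


def footprint(qm: QuantModel) -> MemoryFootprint:
    """Flash/SRAM accounting under a two-buffer ping-pong schedule.

    Flash is the serialized payload length.  For each op, live SRAM is
    input bytes + output bytes (int8) + a 4-byte int32 accumulator per
    output channel (one output tile); SRAM is the peak over ops.
    """
    flash = len(serialize(qm))
    length, channels = qm.input_length, 1
    per_layer: list[dict] = []
    peak = length * channels  # input buffer alone
    for op in qm.ops:
        in_bytes = length * channels
        if op.kind == "conv":
            k, _, F = op.w.shape
            length, channels = length - k + 1, F
            scratch = 4 * channels
        elif op.kind == "maxpool":
            length = length // op.pool
            scratch = 0
        elif op.kind == "flatten":
            length, channels = length * channels, 1
            scratch = 0
        else:  # dense
            length, channels = op.w.shape[1], 1
            scratch = 4 * length
        out_bytes = length * channels
        live = in_bytes + out_bytes + scratch
        per_layer.append({
            "op": op.kind, "in_bytes": in_bytes, "out_bytes": out_bytes,
            "scratch_bytes": scratch, "live_bytes": live,
        })
        peak = max(peak, live)
    return MemoryFootprint(flash_bytes=flash, sram_bytes=peak, per_layer=per_layer)
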