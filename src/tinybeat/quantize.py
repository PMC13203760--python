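"""Post-training full-integer INT8 quantization of a trained float model.

Scheme (standard affine quantization, q = round(x/scale) + zero_point):

* weights: per-tensor symmetric, ``scale = max(|min|, |max|)/127``,
  zero point 0;
* activations: per-tensor asymmetric over the calibrated range, widened
  so that zero is exactly representable;
* biases: int32 at scale ``s_in * s_w``;
* requantization: the real multiplier ``M = s_in * s_w / s_out`` is
  decomposed as ``m0 * 2^-31 * 2^-n`` with ``m0`` in ``[2^30, 2^31)``
  (fixed-point multiplier and right shift), accurate to better than
  2^-24 relative.

Value rounding is half-away-from-zero throughout; the zero point is
computed with round-half-to-even so that a symmetric range maps to zero
point 0 exactly.  Batch normalization is folded into the preceding
convolution before quantization.  Calibration runs the folded model
over a representative sample (default: 200 seeded training segments)
and records per-activation min/max.
"""

from __future__ import annotations

import json
import math
import struct
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cnn import BatchNorm, Conv1D, Dense, Dropout, Flatten, FloatModel, MaxPool1D, ReLU, build_model
from .containers import BeatDataset

_MAGIC = b"TBQ1"
_BN_EPS = 1e-5


class QuantizationError(ValueError):
    """Raised for invalid ranges or missing calibration data."""


@dataclass(frozen=True)
class QuantParams:
    """Affine quantization parameters for one tensor."""

    scale: float
    zero_point: int

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise QuantizationError(f"scale must be positive, got {self.scale}")
        if not -128 <= self.zero_point <= 127:
            raise QuantizationError(f"zero_point {self.zero_point} outside int8 range")


def choose_qparams(rng: tuple[float, float], kind: str = "activations") -> QuantParams:
    """Quantization parameters for a (min, max) range.

    ``kind="weights"``: symmetric, zero point 0.  ``kind="activations"``:
    asymmetric over [min, max] mapped to [-128, 127].
    """
    lo, hi = float(rng[0]), float(rng[1])
    if hi < lo:
        raise QuantizationError(f"invalid range ({lo}, {hi})")
    if kind == "weights":
        absmax = max(abs(lo), abs(hi))
        if absmax == 0:
            raise QuantizationError("all-zero weight tensor has no scale")
        return QuantParams(scale=absmax / 127.0, zero_point=0)
    if kind == "activations":
        if hi == lo:
            raise QuantizationError(f"degenerate activation range ({lo}, {hi})")
        scale = (hi - lo) / 255.0
        # Half-to-even keeps a symmetric range at zero point exactly 0.
        zp = int(np.clip(-128 - np.round(lo / scale), -128, 127))
        return QuantParams(scale=scale, zero_point=zp)
    raise ValueError(f"kind must be 'weights' or 'activations', got {kind!r}")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_value(x: float | np.ndarray, qp: QuantParams) -> np.ndarray:
    """Quantize to int8 with saturation; rounding is half away from zero."""
    q = _round_half_away(np.asarray(x, dtype=np.float64) / qp.scale) + qp.zero_point
    return np.clip(q, -128, 127).astype(np.int8)


def dequantize(q: np.ndarray, qp: QuantParams) -> np.ndarray:
    return (np.asarray(q, dtype=np.float64) - qp.zero_point) * qp.scale


def quantize_multiplier(M: float) -> tuple[int, int]:
    """Decompose M > 0 as ``m0 * 2^-31 * 2^-n`` with m0 in [2^30, 2^31)."""
    if not M > 0:
        raise QuantizationError(f"requantization multiplier must be positive, got {M}")
    frac, exp = math.frexp(M)  # M = frac * 2^exp, frac in [0.5, 1)
    m0 = round(frac * (1 << 31))
    if m0 == 1 << 31:
        m0 >>= 1
        exp += 1
    n = -exp
    return m0, n


# ---------------------------------------------------------------------------
# Batch-norm folding and the inference-op view of a float model
# ---------------------------------------------------------------------------

def fold_batchnorm(model: FloatModel) -> FloatModel:
    """Return an equivalent model with BN folded into preceding convolutions."""
    if not model.architecture.batch_norm_after_conv:
        return model
    folded = build_model(
        replace(model.architecture, batch_norm_after_conv=False), seed=model.seed
    )
    src = [l for l in model.layers if not isinstance(l, (ReLU, MaxPool1D, Flatten, Dropout))]
    dst = [l for l in folded.layers if isinstance(l, (Conv1D, Dense))]
    di = 0
    i = 0
    while i < len(src):
        layer = src[i]
        if isinstance(layer, Conv1D) and i + 1 < len(src) and isinstance(src[i + 1], BatchNorm):
            bn = src[i + 1]
            g = bn.gamma / np.sqrt(bn.running_var + _BN_EPS)
            dst[di].w[...] = layer.w * g  # broadcast over output-channel axis
            dst[di].b[...] = (layer.b - bn.running_mean) * g + bn.beta
            i += 2
        elif isinstance(layer, (Conv1D, Dense)):
            dst[di].w[...] = layer.w
            dst[di].b[...] = layer.b
            i += 1
        else:
            raise QuantizationError("unexpected layer order while folding batch norm")
        di += 1
    folded.history = dict(model.history)
    return folded


def inference_ops(model: FloatModel) -> list[dict]:
    """Flatten a BN-free model into the op sequence the engine executes.

    Ops: ``conv`` / ``dense`` (with ``relu`` flag), ``maxpool``,
    ``flatten``.  ReLU is fused into the producing op.
    """
    if model.architecture.batch_norm_after_conv:
        raise QuantizationError("fold batch norm before building inference ops")
    ops: list[dict] = []
    layers = [l for l in model.layers if not isinstance(l, Dropout)]
    i = 0
    while i < len(layers):
        layer = layers[i]
        if isinstance(layer, (Conv1D, Dense)):
            relu = i + 1 < len(layers) and isinstance(layers[i + 1], ReLU)
            ops.append({
                "kind": "conv" if isinstance(layer, Conv1D) else "dense",
                "w": layer.w, "b": layer.b, "relu": relu,
            })
            i += 2 if relu else 1
        elif isinstance(layer, MaxPool1D):
            ops.append({"kind": "maxpool", "pool": layer.pool})
            i += 1
        elif isinstance(layer, Flatten):
            ops.append({"kind": "flatten"})
            i += 1
        else:
            raise QuantizationError(f"unsupported layer {layer.kind} in inference graph")
    return ops


def _float_op_forward(op: dict, x: np.ndarray) -> np.ndarray:
    if op["kind"] == "conv":
        k = op["w"].shape[0]
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        cols = cols.transpose(0, 1, 3, 2).reshape(x.shape[0], -1, k * x.shape[2])
        out = cols @ op["w"].reshape(-1, op["w"].shape[2]) + op["b"]
    elif op["kind"] == "dense":
        out = x @ op["w"] + op["b"]
    elif op["kind"] == "maxpool":
        B, L, C = x.shape
        lout = L // op["pool"]
        return x[:, : lout * op["pool"], :].reshape(B, lout, op["pool"], C).max(axis=2)
    elif op["kind"] == "flatten":
        return x.reshape(x.shape[0], -1)
    else:  # pragma: no cover
        raise ValueError(op["kind"])
    if op["relu"]:
        out = np.maximum(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def representative_subsample(ds: BeatDataset, n: int = 200, seed: int = 0) -> np.ndarray:
    """Seeded uniform subsample of segments used for calibration."""
    if len(ds) == 0:
        raise QuantizationError("cannot subsample an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ds), size=min(n, len(ds)), replace=False)
    return ds.X[np.sort(idx)]


def calibrate(model: FloatModel, representative: np.ndarray) -> list[tuple[float, float]]:
    """Per-activation (min, max) over the representative set.

    Returns one range per activation point: the network input, then the
    output of every op.  Each range is widened to contain 0 so that zero
    is exactly representable; a degenerate range is widened to a small
    symmetric interval.
    """
    representative = np.asarray(representative, dtype=np.float64)
    if representative.size == 0:
        raise QuantizationError("representative set is empty")
    if representative.ndim == 1:
        representative = representative[None, :]
    folded = fold_batchnorm(model)
    ops = inference_ops(folded)
    x = representative[:, :, None]
    ranges = [(float(x.min()), float(x.max()))]
    for op in ops:
        x = _float_op_forward(op, x)
        ranges.append((float(x.min()), float(x.max())))
    widened = []
    for lo, hi in ranges:
        lo, hi = min(lo, 0.0), max(hi, 0.0)
        if hi == lo:
            lo, hi = -1e-3, 1e-3
        widened.append((lo, hi))
    return widened


# ---------------------------------------------------------------------------
# Conversion
# ---------------------------------------------------------------------------

@dataclass
class QuantOp:
    """One quantized op: weights/bias plus activation and requant constants."""

    kind: str  # conv | dense | maxpool | flatten
    relu: bool = False
    w: np.ndarray | None = None  # int8
    b: np.ndarray | None = None  # int32
    w_qp: QuantParams | None = None
    in_qp: QuantParams | None = None
    out_qp: QuantParams | None = None
    m0: int = 0
    n: int = 0
    pool: int = 2


@dataclass
class QuantModel:
    """Per-tensor affine-quantized int8 model."""

    ops: list[QuantOp]
    input_qp: QuantParams
    alphabet: str = "NVS"
    input_length: int = 250

    @property
    def output_qp(self) -> QuantParams:
        return self.ops[-1].out_qp or self.input_qp


def convert(model: FloatModel, calibration: list[tuple[float, float]]) -> QuantModel:
    """Quantize a trained float model using calibrated activation ranges.

    ``calibration`` must hold one range per activation point as produced
    by :func:`calibrate`.  Int8 weight payload is exactly 25% of the
    float32 payload (1 byte vs 4 per weight element).
    """
    folded = fold_batchnorm(model)
    ops = inference_ops(folded)
    if len(calibration) != len(ops) + 1:
        raise QuantizationError(
            f"need {len(ops) + 1} activation ranges, got {len(calibration)}"
        )
    qps = [choose_qparams(r, "activations") for r in calibration]
    qops: list[QuantOp] = []
    cur_qp = qps[0]
    for op, out_qp_candidate in zip(ops, qps[1:]):
        if op["kind"] in ("conv", "dense"):
            w_qp = choose_qparams((float(op["w"].min()), float(op["w"].max())), "weights")
            wq = quantize_value(op["w"], w_qp)
            bias_scale = cur_qp.scale * w_qp.scale
            bq = np.clip(
                _round_half_away(op["b"] / bias_scale), -(2 ** 31), 2 ** 31 - 1
            ).astype(np.int32)
            out_qp = out_qp_candidate
            m0, n = quantize_multiplier(bias_scale / out_qp.scale)
            qops.append(QuantOp(
                kind=op["kind"], relu=op["relu"], w=wq, b=bq,
                w_qp=w_qp, in_qp=cur_qp, out_qp=out_qp, m0=m0, n=n,
            ))
            cur_qp = out_qp
        elif op["kind"] == "maxpool":
            qops.append(QuantOp(kind="maxpool", pool=op["pool"], in_qp=cur_qp, out_qp=cur_qp))
        else:
            qops.append(QuantOp(kind="flatten", in_qp=cur_qp, out_qp=cur_qp))
    return QuantModel(
        ops=qops, input_qp=qps[0], input_length=model.architecture.input_length
    )


def weight_payload_bytes(qm: QuantModel) -> int:
    """Bytes of int8 weight tensors (the quantized payload)."""
    return int(sum(op.w.size for op in qm.ops if op.w is not None))


def float_weight_payload_bytes(model: FloatModel) -> int:
    """Bytes the same weight tensors occupy at float32 precision."""
    ops = inference_ops(fold_batchnorm(model))
    return int(sum(4 * op["w"].size for op in ops if "w" in op))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def serialize(qm: QuantModel) -> bytes:
    """Serialize to the portable byte form (also the model.h payload)."""
    meta_ops = []
    blobs: list[bytes] = []
    for op in qm.ops:
        d: dict = {"kind": op.kind, "relu": op.relu, "pool": op.pool}
        if op.w is not None:
            d.update(
                w_shape=list(op.w.shape),
                w_scale=op.w_qp.scale,
                in_scale=op.in_qp.scale, in_zp=op.in_qp.zero_point,
                out_scale=op.out_qp.scale, out_zp=op.out_qp.zero_point,
                m0=op.m0, n=op.n,
            )
            blobs.append(op.w.astype("<i1").tobytes())
            blobs.append(op.b.astype("<i4").tobytes())
        meta_ops.append(d)
    meta = {
        "alphabet": qm.alphabet,
        "input_length": qm.input_length,
        "input_scale": qm.input_qp.scale,
        "input_zp": qm.input_qp.zero_point,
        "ops": meta_ops,
    }
    meta_b = json.dumps(meta, sort_keys=True).encode()
    return _MAGIC + struct.pack("<I", len(meta_b)) + meta_b + b"".join(blobs)


def deserialize(raw: bytes) -> QuantModel:
    if raw[:4] != _MAGIC:
        raise QuantizationError("not a quantized-model container (bad magic)")
    (meta_len,) = struct.unpack("<I", raw[4:8])
    meta = json.loads(raw[8 : 8 + meta_len].decode())
    off = 8 + meta_len
    input_qp = QuantParams(meta["input_scale"], meta["input_zp"])
    ops: list[QuantOp] = []
    for d in meta["ops"]:
        if "w_shape" in d:
            shape = tuple(d["w_shape"])
            nw = int(np.prod(shape))
            w = np.frombuffer(raw[off : off + nw], dtype="<i1").reshape(shape).copy()
            off += nw
            nb = shape[-1]
            b = np.frombuffer(raw[off : off + 4 * nb], dtype="<i4").copy()
            off += 4 * nb
            ops.append(QuantOp(
                kind=d["kind"], relu=d["relu"], w=w, b=b,
                w_qp=QuantParams(d["w_scale"], 0),
                in_qp=QuantParams(d["in_scale"], d["in_zp"]),
                out_qp=QuantParams(d["out_scale"], d["out_zp"]),
                m0=d["m0"], n=d["n"],
            ))
        else:
            qp = ops[-1].out_qp if ops else input_qp
            ops.append(QuantOp(kind=d["kind"], pool=d["pool"], in_qp=qp, out_qp=qp))
    if off != len(raw):
        raise QuantizationError(f"container length mismatch ({off} != {len(raw)})")
    return QuantModel(
        ops=ops, input_qp=input_qp,
        alphabet=meta["alphabet"], input_length=meta["input_length"],
    )


def export_portable(qm: QuantModel, path: str | Path) -> None:
    Path(path).write_bytes(serialize(qm))


def load_portable(path: str | Path) -> QuantModel:
    return deserialize(Path(path).read_bytes())


def export_c_header(qm: QuantModel, array_name: str = "model") -> str:
    """xxd-style C header embedding the serialized model."""
    raw = serialize(qm)
    lines = [f"unsigned char {array_name}[] = {{"]
    for i in range(0, len(raw), 12):
        chunk = ", ".join(f"0x{b:02x}" for b in raw[i : i + 12])
        lines.append(f"  {chunk},")
    lines[-1] = lines[-1].rstrip(",") if len(raw) else lines[-1]
    lines.append("};")
    lines.append(f"unsigned int {array_name}_len = {len(raw)};")
    return "\n".join(lines) + "\n"
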