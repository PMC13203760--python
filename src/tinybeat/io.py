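"""WFDB-format ECG input/output and beat-dataset serialization.

Implements the subset of the PhysioNet WFDB family the pipeline needs:
``.hea`` headers, ``.dat`` signal files in formats 16 (int16) and 212
(packed 12-bit, the MIT-BIH native format), and MIT-format ``.atr``
annotation files.  Amplitudes are converted to physical units (mV) via
the header gain/baseline.  Records the package writes itself use format
16 with gain 200 adu/mV, so a write/read round trip is exact to the
0.005 mV quantization step.

Also maps database beat symbols onto the reduced three-class scheme
(N, V, S; everything else excluded) and serializes beat datasets.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from .containers import BeatDataset, BeatLabel, EcgRecord

logger = logging.getLogger(__name__)

_DATASET_VERSION = 1


class FormatError(ValueError):
    """Raised on a missing, corrupt or version-mismatched file."""


# Beat symbols grouped per the AAMI taxonomy, reduced to three classes:
# normal-conduction beats -> N, supraventricular ectopics -> S,
# ventricular ectopics -> V.  Fusion, paced, unknown and non-beat marks
# are excluded.
_SYMBOL_CLASS = {
    "N": BeatLabel.N, "L": BeatLabel.N, "R": BeatLabel.N, "e": BeatLabel.N, "j": BeatLabel.N,
    "A": BeatLabel.S, "a": BeatLabel.S, "J": BeatLabel.S, "S": BeatLabel.S,
    "V": BeatLabel.V, "E": BeatLabel.V,
}

# MIT annotation code <-> symbol table (beat and common non-beat codes).
_CODE_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|", 18: "s", 19: "T",
    20: "*", 21: "D", 22: '"', 23: "=", 24: "p", 25: "B", 26: "^", 27: "t",
    28: "+", 29: "u", 30: "?", 31: "!", 32: "[", 33: "]", 34: "e", 35: "n",
    36: "@", 37: "x", 38: "f", 39: "(", 40: ")", 41: "r",
}
_SYMBOL_CODE = {s: c for c, s in _CODE_SYMBOL.items()}

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def map_annotation_symbol(symbol: str, table: dict[str, BeatLabel] | None = None) -> BeatLabel:
    """Map a single-character beat symbol to the three-class scheme.

    Total and deterministic: unknown symbols map to ``EXCLUDED``.  An
    alternative grouping can be supplied via ``table``.
    """
    if len(symbol) != 1:
        raise ValueError(f"symbol must be a single character, got {symbol!r}")
    return (table or _SYMBOL_CLASS).get(symbol, BeatLabel.EXCLUDED)


# ---------------------------------------------------------------------------
# Header parsing / writing
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    try:
        lines = [
            ln.strip() for ln in hea_path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {hea_path}: {exc}") from exc
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    rec_tokens = lines[0].split()
    if len(rec_tokens) < 2:
        raise FormatError(f"malformed record line in {hea_path}")
    record_id = rec_tokens[0].split("/")[0]
    n_sig = int(rec_tokens[1])
    fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
    n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    if n_sig < 1:
        raise FormatError(f"record {record_id} declares zero signal channels")
    if len(lines) < 1 + n_sig:
        raise FormatError(f"header {hea_path} truncated: {n_sig} channels declared")

    channels = []
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed signal line {ln!r} in {hea_path}")
        fname, fmt = tok[0], tok[1].split("x")[0].split(":")[0]
        gain_spec = tok[2] if len(tok) > 2 else "200"
        gain_str = gain_spec.split("/")[0]
        baseline = None
        if "(" in gain_str:
            gain_str, rest = gain_str.split("(")
            baseline = int(rest.rstrip(")"))
        gain = float(gain_str) or 200.0
        adc_zero = int(tok[4]) if len(tok) > 4 else 0
        if baseline is None:
            baseline = adc_zero
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(channels)}"
        channels.append(
            {"file": fname, "fmt": int(fmt), "gain": gain, "baseline": baseline, "desc": desc}
        )
    return record_id, fs, n_samples, channels


def _read_dat(dat_path: Path, fmt: int, n_sig: int) -> np.ndarray:
    """Read an interleaved multi-channel .dat file; returns (n, n_sig) int array."""
    raw = dat_path.read_bytes()
    if fmt == 16:
        data = np.frombuffer(raw[: len(raw) - len(raw) % (2 * n_sig)], dtype="<i2")
        return data.reshape(-1, n_sig).astype(np.int32)
    if fmt == 212:
        usable = len(raw) - len(raw) % 3
        b = np.frombuffer(raw[:usable], dtype=np.uint8).reshape(-1, 3).astype(np.int32)
        s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s1 = ((b[:, 1] >> 4) << 8) | b[:, 2]
        s0 = np.where(s0 > 2047, s0 - 4096, s0)
        s1 = np.where(s1 > 2047, s1 - 4096, s1)
        flat = np.empty(2 * len(b), dtype=np.int32)
        flat[0::2], flat[1::2] = s0, s1
        flat = flat[: len(flat) - len(flat) % n_sig]
        return flat.reshape(-1, n_sig)
    raise FormatError(f"unsupported WFDB signal format {fmt}")


def read_annotations(ann_path: Path) -> list[tuple[int, str]]:
    """Read an MIT-format annotation file into (sample_index, symbol) pairs."""
    raw = ann_path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(raw):
        low, high = raw[i], raw[i + 1]
        i += 2
        code = high >> 2
        interval = ((high & 0x03) << 8) | low
        if code == 0 and interval == 0:
            break
        if code == _SKIP:
            if i + 4 > len(raw):
                raise FormatError(f"truncated SKIP in {ann_path}")
            hi = struct.unpack("<h", raw[i : i + 2])[0]
            lo = struct.unpack("<H", raw[i + 2 : i + 4])[0]
            t += (hi << 16) | lo
            i += 4
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += interval + (interval & 1)  # aux string, padded to even length
            continue
        t += interval
        out.append((t, _CODE_SYMBOL.get(code, "Q")))
    return out


def write_annotations(ann_path: Path, annotations: list[tuple[int, str]]) -> None:
    """Write (sample_index, symbol) pairs as an MIT-format annotation file."""
    buf = bytearray()
    prev = 0
    for idx, sym in annotations:
        code = _SYMBOL_CODE.get(sym, 13)  # unknown symbols stored as 'Q'
        diff = idx - prev
        if diff < 0:
            raise ValueError("annotation indices must be non-decreasing")
        if diff > 1023:
            buf += struct.pack("<H", _SKIP << 10)
            buf += struct.pack("<h", (diff >> 16) & 0xFFFF if diff >> 16 < 0x8000 else diff >> 16)
            buf += struct.pack("<H", diff & 0xFFFF)
            diff = 0
        buf += struct.pack("<H", (code << 10) | diff)
        prev = idx
    buf += b"\x00\x00"
    ann_path.write_bytes(bytes(buf))


def read_wfdb_record(path: str | Path, lead_preference: str = "MLII") -> EcgRecord:
    """Read one channel of a WFDB record, preferring the named lead.

    Selects the channel whose description matches ``lead_preference``
    (``"MLII"`` also matches ``"II"``); if absent, falls back to channel 0
    with a logged warning.  Amplitudes are converted to mV via
    ``(adc - baseline) / gain``.  Annotations from a sibling ``.atr``
    file are attached when present.
    """
    path = Path(path)
    hea_path = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea_path.exists():
        raise FormatError(f"WFDB header not found: {hea_path}")
    record_id, fs, _, channels = _parse_header(hea_path)

    wanted = {lead_preference}
    if lead_preference in ("MLII", "II"):
        wanted |= {"MLII", "II"}
    ch_idx = next((i for i, ch in enumerate(channels) if ch["desc"] in wanted), None)
    if ch_idx is None:
        logger.warning(
            "record %s has no %s channel (found %s); falling back to channel 0",
            record_id, lead_preference, [ch["desc"] for ch in channels],
        )
        ch_idx = 0
    ch = channels[ch_idx]

    dat_path = hea_path.parent / ch["file"]
    if not dat_path.exists():
        raise FormatError(f"WFDB signal file not found: {dat_path}")
    adc = _read_dat(dat_path, ch["fmt"], len(channels))[:, ch_idx]
    signal = (adc - ch["baseline"]) / ch["gain"]

    annotations: list[tuple[int, str]] = []
    atr_path = hea_path.with_suffix(".atr")
    if atr_path.exists():
        annotations = [(i, s) for i, s in read_annotations(atr_path) if i < signal.size]

    return EcgRecord(
        record_id=record_id, signal=signal, fs=fs,
        lead=ch["desc"], annotations=annotations,
    )


def write_wfdb_record(record: EcgRecord, directory: str | Path, gain: float = 200.0) -> Path:
    """Write a record as WFDB format-16 files (.hea/.dat, .atr if annotated).

    Returns the header path.  With the default gain, amplitudes are stored
    at a 1/200 mV step, so a read-back reproduces values to within 0.0025 mV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rid = record.record_id
    adc = np.clip(np.round(record.signal * gain), -32768, 32767).astype("<i2")
    (directory / f"{rid}.dat").write_bytes(adc.tobytes())
    n = record.signal.size
    fs = record.fs
    fs_str = f"{fs:g}"
    hea = (
        f"{rid} 1 {fs_str} {n}\n"
        f"{rid}.dat 16 {gain:g}(0)/mV 16 0 {int(adc[0])} 0 0 {record.lead}\n"
    )
    (directory / f"{rid}.hea").write_text(hea)
    if record.annotations:
        write_annotations(directory / f"{rid}.atr", record.annotations)
    return directory / f"{rid}.hea"


# ---------------------------------------------------------------------------
# Beat-dataset container
# ---------------------------------------------------------------------------

def save_dataset(ds: BeatDataset, path: str | Path) -> None:
    """Serialize a BeatDataset to a single .npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        version=np.int64(_DATASET_VERSION),
        X=ds.X,
        y=ds.y,
        r_index=ds.r_index,
        record_id=np.asarray(ds.record_id, dtype=object),
        provenance=np.str_(ds.provenance),
        seed=np.int64(-1 if ds.seed is None else ds.seed),
        labels_known=np.bool_(ds.labels_known),
    )


def load_dataset(path: str | Path) -> BeatDataset:
    """Load a BeatDataset written by :func:`save_dataset` (lossless)."""
    path = Path(path)
    try:
        with np.load(path, allow_pickle=True) as z:
            version = int(z["version"])
            if version != _DATASET_VERSION:
                raise FormatError(
                    f"dataset container version {version} != supported {_DATASET_VERSION}"
                )
            seed = int(z["seed"])
            return BeatDataset(
                X=z["X"],
                y=z["y"],
                r_index=z["r_index"],
                record_id=[str(r) for r in z["record_id"]],
                provenance=str(z["provenance"]),
                seed=None if seed < 0 else seed,
                labels_known=bool(z["labels_known"]),
            )
    except FormatError:
        raise
    except Exception as exc:  # truncated/corrupt archive
        raise FormatError(f"cannot load dataset container {path}: {exc}") from exc
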