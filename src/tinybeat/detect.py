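"""Pan-Tompkins R-peak detection and 250-sample beat segmentation.

The detector follows the classic chain on an already band-pass-filtered
signal: five-point derivative, squaring, moving-window integration
(150 ms), then an adaptive threshold with running signal/noise peak
estimates and a 200 ms refractory period:

    spk <- 0.125 * peak + 0.875 * spk        (accepted signal peaks)
    npk <- 0.125 * peak + 0.875 * npk        (rejected noise peaks)
    threshold = npk + 0.25 * (spk - npk)

Accepted detections are refined to the local maximum of the filtered
signal within +/-100 ms, so the stored index is the R apex.  No
search-back second-threshold stage is used.

Segmentation extracts half-open windows [r-125, r+125) (250 samples,
about 0.7 s at 360 Hz), min-max normalises each window, and drops beats
without full context, flat windows, and excluded labels — all counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .containers import (
    BeatDataset,
    BeatLabel,
    BeatSegment,
    EcgRecord,
    SEGMENT_LENGTH,
    SEGMENT_R_INDEX,
)
from .io import map_annotation_symbol
from .preprocess import DegenerateSegmentError, minmax_normalize

logger = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Tunable Pan-Tompkins parameters (classic published values)."""

    integration_ms: float = 150.0
    refractory_ms: float = 200.0
    threshold_fraction: float = 0.25
    peak_update: float = 0.125
    refine_ms: float = 100.0


def _pan_tompkins_feature(signal: np.ndarray, fs: float, cfg: DetectorConfig) -> np.ndarray:
    """Derivative -> squaring -> moving-window integration."""
    # Five-point derivative (1/8)[-1 -2 0 2 1] scaled by fs/8; zero-phase
    # alignment via symmetric kernel placement.
    h = np.array([-1.0, -2.0, 0.0, 2.0, 1.0]) * fs / 8.0
    deriv = np.convolve(signal, h[::-1], mode="same")
    squared = deriv * deriv
    win = max(1, int(round(cfg.integration_ms / 1000.0 * fs)))
    kernel = np.ones(win) / win
    return np.convolve(squared, kernel, mode="same")


def pan_tompkins_detect(
    signal: np.ndarray, fs: float, cfg: DetectorConfig | None = None
) -> np.ndarray:
    """Detect R-peak sample indices in a band-pass-filtered signal.

    Returns strictly increasing indices with no two closer than the
    refractory period, each refined to the local maximum of ``signal``
    within +/-``refine_ms``.
    """
    cfg = cfg or DetectorConfig()
    signal = np.asarray(signal, dtype=np.float64)
    if fs <= 0:
        raise ValueError("fs must be positive")
    win = max(1, int(round(cfg.integration_ms / 1000.0 * fs)))
    if signal.size < win or not np.any(signal):
        logger.warning("signal too short or all-zero: no beats detected")
        return np.array([], dtype=np.int64)

    mwi = _pan_tompkins_feature(signal, fs, cfg)
    refractory = int(round(cfg.refractory_ms / 1000.0 * fs))
    candidates, _ = find_peaks(mwi, distance=max(1, refractory))
    if candidates.size == 0:
        return np.array([], dtype=np.int64)

    # Initialise running estimates from the learning phase (first 2 s).
    learn = mwi[: int(2 * fs)] if mwi.size > int(2 * fs) else mwi
    spk = float(learn.max())
    npk = float(learn.mean()) / 2.0
    a = cfg.peak_update

    accepted: list[int] = []
    refine = int(round(cfg.refine_ms / 1000.0 * fs))
    for c in candidates:
        peak = mwi[c]
        threshold = npk + cfg.threshold_fraction * (spk - npk)
        if peak > threshold:
            lo, hi = max(c - refine, 0), min(c + refine + 1, signal.size)
            r = lo + int(np.argmax(signal[lo:hi]))
            if accepted and r - accepted[-1] < refractory:
                # Keep the larger of the two colliding refined peaks.
                if signal[r] > signal[accepted[-1]]:
                    accepted[-1] = r
            else:
                accepted.append(r)
            spk = a * peak + (1 - a) * spk
        else:
            npk = a * peak + (1 - a) * npk
    return np.unique(np.array(accepted, dtype=np.int64))


def segment_beats(
    record: EcgRecord,
    r_indices: np.ndarray,
    labels: list[BeatLabel] | None = None,
) -> tuple[list[BeatSegment], dict[str, int]]:
    """Extract normalised 250-sample windows [r-125, r+125).

    Beats with insufficient context, flat windows, or EXCLUDED labels are
    dropped; the second return value counts kept and dropped beats so
    that kept + dropped == input.
    """
    r_indices = np.asarray(r_indices, dtype=np.int64)
    if labels is not None and len(labels) != r_indices.size:
        raise ValueError("labels must align with r_indices")
    n = record.signal.size
    counts = {"kept": 0, "dropped_context": 0, "dropped_flat": 0, "dropped_excluded": 0}
    out: list[BeatSegment] = []
    for k, r in enumerate(r_indices):
        label = labels[k] if labels is not None else BeatLabel.N
        if label == BeatLabel.EXCLUDED:
            counts["dropped_excluded"] += 1
            continue
        lo, hi = r - SEGMENT_R_INDEX, r + (SEGMENT_LENGTH - SEGMENT_R_INDEX)
        if lo < 0 or hi > n:
            counts["dropped_context"] += 1
            continue
        try:
            normalized, _ = minmax_normalize(record.signal[lo:hi])
        except DegenerateSegmentError:
            counts["dropped_flat"] += 1
            continue
        out.append(BeatSegment(normalized, label, int(r), record.record_id))
        counts["kept"] += 1
    dropped = sum(v for k, v in counts.items() if k != "kept")
    if dropped:
        logger.info("segment_beats: kept %d, dropped %d (%s)", counts["kept"], dropped, counts)
    return out, counts


def build_dataset(
    records: list[EcgRecord],
    mode: str = "annotations",
    detector: DetectorConfig | None = None,
    provenance: str = "synthetic",
    seed: int | None = None,
) -> BeatDataset:
    """Build a BeatDataset from filtered records.

    ``mode="annotations"`` centres windows on annotation R samples with
    mapped labels (training path); ``mode="detected"`` centres on
    detector output with labels unknown (inference path).
    """
    if mode not in ("annotations", "detected"):
        raise ValueError(f"mode must be 'annotations' or 'detected', got {mode!r}")
    segments: list[BeatSegment] = []
    for rec in records:
        if mode == "annotations":
            if not rec.annotations:
                raise ValueError(f"record {rec.record_id} has no annotations")
            r_idx = np.array([i for i, _ in rec.annotations], dtype=np.int64)
            labels = [map_annotation_symbol(s) for _, s in rec.annotations]
        else:
            r_idx = pan_tompkins_detect(rec.signal, rec.fs, detector)
            labels = None
        segs, _ = segment_beats(rec, r_idx, labels)
        segments.extend(segs)
    if not segments:
        logger.warning("build_dataset produced an empty dataset")
    labels_known = mode == "annotations"
    return BeatDataset(
        X=np.array([s.samples for s in segments]).reshape(-1, SEGMENT_LENGTH),
        y=np.array([int(s.label) for s in segments], dtype=np.int64),
        r_index=np.array([s.r_index for s in segments], dtype=np.int64),
        record_id=[s.record_id for s in segments],
        provenance=provenance,
        seed=seed,
        labels_known=labels_known,
    )
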