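"""Core data containers shared across the pipeline.

The pipeline operates on single-lead ECG at 360 Hz.  A record carries the
sampled signal plus beat annotations (sample index of the R peak and a
single-character beat symbol); a beat segment is one 250-sample window
centred on an R peak, min-max normalised to [0, 1]; a beat dataset is the
matrix of such segments with their class labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Number of samples in one heartbeat window (125 before + 125 after the R peak).
SEGMENT_LENGTH = 250
#: Local index of the R apex inside a segment.
SEGMENT_R_INDEX = 125
#: Default sampling rate in Hz.
DEFAULT_FS = 360.0


class BeatLabel(enum.IntEnum):
    """Three-class beat taxonomy plus an exclusion sentinel.

    The reduced scheme keeps Normal (N), Ventricular ectopic (V) and
    Supraventricular ectopic (S); fusion, paced, unknown and non-beat
    annotations are EXCLUDED and never enter training or evaluation.
    """

    N = 0
    V = 1
    S = 2
    EXCLUDED = 3


#: Class alphabet in fixed one-hot order.
CLASS_ALPHABET = (BeatLabel.N, BeatLabel.V, BeatLabel.S)
N_CLASSES = len(CLASS_ALPHABET)


@dataclass
class EcgRecord:
    """Single-lead sampled ECG with optional beat annotations.

    Annotations are ``(sample_index, symbol)`` pairs with strictly
    increasing 0-based sample indices; the index marks the R-peak sample.
    """

    record_id: str
    signal: np.ndarray  # shape (n,), amplitudes in mV
    fs: float = DEFAULT_FS
    lead: str = "MLII"
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 1 or self.signal.size < 1:
            raise ValueError("signal must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        prev = -1
        for idx, sym in self.annotations:
            if not (prev < idx < self.signal.size):
                raise ValueError(
                    f"annotation index {idx} not strictly increasing within signal bounds"
                )
            if len(sym) != 1:
                raise ValueError(f"annotation symbol must be one character, got {sym!r}")
            prev = idx

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


@dataclass
class BeatSegment:
    """One normalised 250-sample heartbeat window."""

    samples: np.ndarray  # shape (250,), values in [0, 1]
    label: BeatLabel
    r_index: int  # index into the source record
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.shape != (SEGMENT_LENGTH,):
            raise ValueError(
                f"segment must have exactly {SEGMENT_LENGTH} samples, got {self.samples.shape}"
            )


@dataclass
class BeatDataset:
    """A labelled collection of beat segments in matrix form.

    ``X`` is the (n, 250) segment matrix, ``y`` the integer labels in the
    (N, V, S) alphabet.  ``labels_known`` is False on the inference path
    (detector-segmented data with no annotations), in which case ``y`` is
    all zeros and must not be used for training or scoring.
    """

    X: np.ndarray
    y: np.ndarray
    r_index: np.ndarray
    record_id: list[str]
    provenance: str = "synthetic"  # "real" | "synthetic"
    seed: int | None = None
    labels_known: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64).reshape(-1, SEGMENT_LENGTH)
        self.y = np.asarray(self.y, dtype=np.int64).reshape(-1)
        self.r_index = np.asarray(self.r_index, dtype=np.int64).reshape(-1)
        n = self.X.shape[0]
        if not (self.y.size == self.r_index.size == len(self.record_id) == n):
            raise ValueError("dataset field lengths disagree")
        if self.labels_known and n and not np.isin(self.y, [0, 1, 2]).all():
            raise ValueError("labels must be in the {N, V, S} alphabet")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> dict[BeatLabel, int]:
        return {c: int(np.sum(self.y == int(c))) for c in CLASS_ALPHABET}

    def subset(self, indices: np.ndarray) -> "BeatDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return BeatDataset(
            X=self.X[indices],
            y=self.y[indices],
            r_index=self.r_index[indices],
            record_id=[self.record_id[i] for i in indices],
            provenance=self.provenance,
            seed=self.seed,
            labels_known=self.labels_known,
        )

    @property
    def segments(self) -> list[BeatSegment]:
        return [
            BeatSegment(self.X[i], BeatLabel(int(self.y[i])), int(self.r_index[i]), self.record_id[i])
            for i in range(len(self))
        ]
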