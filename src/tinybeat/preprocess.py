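"""Band-pass filtering and per-segment amplitude normalization.

The conditioning chain is a fourth-order Butterworth band-pass
(0.5–40 Hz by default) applied forward-backward for zero net phase, so
QRS landmarks are not shifted, followed by per-heartbeat min-max
scaling to [0, 1]:

    x_norm(t) = (x(t) - x_min) / (x_max - x_min)

with x_min/x_max taken within each individual heartbeat window.  The
filter is realised as cascaded second-order sections with even-extension
edge padding, which keeps the 0.5 Hz corner numerically stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class DegenerateSegmentError(ValueError):
    """Raised for a constant (flat) segment, whose normalization is undefined."""


@dataclass
class FilterSpec:
    """A designed Butterworth band-pass in second-order-section form."""

    order: int
    low_cut: float
    high_cut: float
    fs: float
    sos: np.ndarray

    def magnitude_response(self, freqs: np.ndarray) -> np.ndarray:
        """Single-pass magnitude response at the given frequencies (Hz)."""
        _, h = sps.sosfreqz(self.sos, worN=np.atleast_1d(freqs), fs=self.fs)
        return np.abs(h)


def design_bandpass(
    order: int = 4, low_cut: float = 0.5, high_cut: float = 40.0, fs: float = 360.0
) -> FilterSpec:
    """Design the Butterworth band-pass filter.

    ``order`` is the overall band-pass order (the classic "fourth-order
    band-pass": a second-order low-pass prototype transformed to
    band-pass).
    """
    if not (0 < low_cut < high_cut < fs / 2):
        raise ValueError(
            f"need 0 < low_cut < high_cut < fs/2, got ({low_cut}, {high_cut}) at fs={fs}"
        )
    if order < 2 or order % 2:
        raise ValueError(f"order must be even and >= 2, got {order}")
    sos = sps.butter(order // 2, [low_cut, high_cut], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(order=order, low_cut=low_cut, high_cut=high_cut, fs=fs, sos=sos)


def filter_zero_phase(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply the filter forward and backward (zero net phase shift).

    Output length equals input length; the effective magnitude response
    is the square of the single-pass response.  Requires
    ``len(x) > 3 * order`` for the edge padding.
    """
    x = np.asarray(x, dtype=np.float64)
    padlen = 3 * (spec.order + 1)
    if x.size <= padlen:
        raise ValueError(f"signal too short to filter: {x.size} <= padlen {padlen}")
    return sps.sosfiltfilt(spec.sos, x, padtype="even", padlen=padlen)


def minmax_normalize(segment: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale a heartbeat segment to [0, 1]; returns ``(normalized, (x_min, x_max))``.

    Raises :class:`DegenerateSegmentError` for a constant segment (the
    caller drops such segments and counts them).
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.size == 0:
        raise ValueError("cannot normalize an empty segment")
    x_min, x_max = float(segment.min()), float(segment.max())
    if x_max == x_min:
        raise DegenerateSegmentError(f"flat segment (constant value {x_min})")
    return (segment - x_min) / (x_max - x_min), (x_min, x_max)
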