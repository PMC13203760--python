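"""Synthetic single-lead ECG with known R positions and beat classes.

Beats are modelled as sums of Gaussian bumps (P, Q, R, S, T waves), in
the spirit of dynamical ECG simulators but simplified so that ground
truth is exact: the R apex sample and the class of every beat are known
by construction.  Class morphologies follow textbook criteria:

* **N** — full PQRST with a narrow QRS (< 40 ms at half R amplitude);
* **V** — wide QRS (>= 120 ms equivalent), no P wave, discordant
  (inverted) T wave, premature timing;
* **S** — narrow QRS like N but with an absent P wave and a shortened
  coupling interval (premature beat of supraventricular origin).

Noise terms emulate the three dominant ECG artefacts: baseline wander
(default 0.3 Hz, below the 0.5 Hz filter corner), powerline interference
(default 60 Hz, above the 40 Hz corner) and white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BeatLabel, DEFAULT_FS, EcgRecord

_LABEL_SYMBOL = {BeatLabel.N: "N", BeatLabel.V: "V", BeatLabel.S: "A"}


@dataclass
class NoiseConfig:
    """Additive noise amplitudes (mV) and frequencies (Hz)."""

    baseline_wander_amp: float = 0.10
    baseline_wander_freq: float = 0.3
    powerline_amp: float = 0.05
    powerline_freq: float = 60.0
    white_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("baseline_wander_amp", "powerline_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SynthConfig:
    """Conditions for one synthetic record."""

    fs: float = DEFAULT_FS
    n_beats: int = 60
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # (N, V, S)
    mean_hr: float = 72.0  # beats/min
    hr_jitter: float = 0.08  # fractional RR jitter
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {self.class_mix}")
        if any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix proportions must be non-negative")


# Per-class wave templates: (amplitude mV, centre s relative to R, width sigma s).
# V: sigma 0.052 s gives a QRS full width at half maximum of ~122 ms.
_TEMPLATES: dict[BeatLabel, list[tuple[float, float, float]]] = {
    BeatLabel.N: [
        (0.15, -0.170, 0.022),   # P
        (-0.12, -0.028, 0.008),  # Q
        (1.00, 0.000, 0.010),    # R
        (-0.25, 0.030, 0.009),   # S
        (0.30, 0.250, 0.055),    # T
    ],
    BeatLabel.V: [
        (1.20, -0.025, 0.020),   # wide biphasic complex, no P:
        (1.00, 0.045, 0.042),    #   two merged bumps, >=120 ms at half max
        (-0.45, 0.310, 0.070),   # discordant T
    ],
    BeatLabel.S: [
        (-0.12, -0.028, 0.008),  # Q (no P)
        (0.95, 0.000, 0.010),    # R
        (-0.22, 0.030, 0.009),   # S
        (0.28, 0.240, 0.050),    # T
    ],
}

#: Beat support relative to the R apex, seconds.
_BEAT_SPAN = (-0.30, 0.45)


def generate_beat(
    label: BeatLabel, fs: float = DEFAULT_FS, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Generate one beat waveform; returns ``(waveform, r_offset)``.

    ``r_offset`` is the sample index of the R apex within the waveform
    (the global maximum of the noiseless beat).  When ``rng`` is given,
    amplitudes and widths are jittered by ~5% to emulate beat-to-beat
    variability; with ``rng=None`` the pure template is returned.
    """
    if label not in _TEMPLATES:
        raise ValueError(f"cannot generate a beat for label {label!r}")
    n = int(round((_BEAT_SPAN[1] - _BEAT_SPAN[0]) * fs))
    t = np.arange(n) / fs + _BEAT_SPAN[0]
    wave = np.zeros(n)
    for amp, mu, sigma in _TEMPLATES[label]:
        if rng is not None:
            amp = amp * (1 + 0.05 * rng.standard_normal())
            sigma = sigma * (1 + 0.05 * rng.standard_normal())
        wave += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return wave, int(np.argmax(wave))


def generate_record(cfg: SynthConfig) -> tuple[EcgRecord, list[tuple[int, BeatLabel]]]:
    """Generate a synthetic annotated record and its ground truth.

    Beats are placed at RR intervals drawn from ``mean_hr`` with uniform
    fractional jitter; S beats shorten their coupling interval by 25%
    and V beats by 15% (premature beats).  Returns the record (with
    annotations equal to the truth) and the ``(r_index, label)`` list.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    labels = [
        (BeatLabel.N, BeatLabel.V, BeatLabel.S)[k]
        for k in rng.choice(3, size=cfg.n_beats, p=np.asarray(cfg.class_mix))
    ]

    rr_base = 60.0 / cfg.mean_hr
    r_times = []
    t = 0.5  # lead-in so the first beat has left context
    for lab in labels:
        rr = rr_base * (1 + cfg.hr_jitter * rng.uniform(-1, 1))
        if lab is BeatLabel.S:
            rr *= 0.75
        elif lab is BeatLabel.V:
            rr *= 0.85
        t += rr
        r_times.append(t)

    n_samples = int(round((r_times[-1] + 0.6) * fs))
    signal = np.zeros(n_samples)
    truth: list[tuple[int, BeatLabel]] = []
    for t_r, lab in zip(r_times, labels):
        wave, r_off = generate_beat(lab, fs, rng)
        r_idx = int(round(t_r * fs))
        start = r_idx - r_off
        lo, hi = max(start, 0), min(start + wave.size, n_samples)
        signal[lo:hi] += wave[lo - start : hi - start]
        truth.append((r_idx, lab))

    nz = cfg.noise
    ts = np.arange(n_samples) / fs
    if nz.baseline_wander_amp > 0:
        signal += nz.baseline_wander_amp * np.sin(
            2 * np.pi * nz.baseline_wander_freq * ts + rng.uniform(0, 2 * np.pi)
        )
    if nz.powerline_amp > 0:
        signal += nz.powerline_amp * np.sin(
            2 * np.pi * nz.powerline_freq * ts + rng.uniform(0, 2 * np.pi)
        )
    if nz.white_sd > 0:
        signal += nz.white_sd * rng.standard_normal(n_samples)

    record = EcgRecord(
        record_id=f"synth{cfg.seed:05d}",
        signal=signal,
        fs=fs,
        lead="MLII",
        annotations=[(idx, _LABEL_SYMBOL[lab]) for idx, lab in truth],
    )
    return record, truth
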