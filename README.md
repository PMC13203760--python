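# tinybeat

A self-contained TinyML pipeline for single-lead ECG heartbeat
classification, aimed at microcontroller-class deployment: no deep
learning framework, no external dataset, no floating-point unit needed
at inference time.

## Who this is for

Researchers and engineers prototyping embedded arrhythmia screening —
classifying individual heartbeats into **Normal (N)**, **Ventricular
ectopic (V)** and **Supraventricular ectopic (S)** — who need every
stage of the pipeline to be transparent, testable and reproducible on a
laptop: signal conditioning, QRS detection, a compact neural classifier,
full-integer quantization, and an emulation of the integer-only
arithmetic a flash-constrained microcontroller would execute.

## What it does

1. **Synthetic ECG generation** — 360 Hz single-lead records built from
   Gaussian-bump PQRST templates with class-specific morphology (wide
   biphasic QRS for V, absent P and shortened coupling for S), baseline
   wander, powerline interference and white noise, with exact
   ground-truth R positions and labels.
2. **WFDB I/O** — reads `.hea`/`.dat` (formats 16 and 212) and
   MIT-format `.atr` annotation files; maps beat symbols onto the
   reduced three-class scheme ({N,L,R,e,j}→N, {A,a,J,S}→S, {V,E}→V,
   everything else excluded).
3. **Preprocessing** — fourth-order Butterworth band-pass (0.5–40 Hz)
   applied forward-backward (zero phase), then per-heartbeat min–max
   normalization `x_norm = (x − x_min)/(x_max − x_min)` to [0, 1].
4. **Beat detection & segmentation** — the classic Pan–Tompkins chain
   (five-point derivative, squaring, 150 ms moving-window integration,
   adaptive threshold `npk + 0.25·(spk − npk)` with a 200 ms refractory
   period), then 250-sample windows `[r−125, r+125)` (≈0.7 s at 360 Hz).
5. **Compact 1D-CNN** — Conv1D(16,3)→MaxPool(2)→Conv1D(32,3)→Flatten
   →Dense(64)→Dense(3, softmax), with batch normalization and 20%
   dropout; trained with Adam (lr 0.001, batch 32, up to 100 epochs,
   early stopping patience 10) in pure NumPy.
6. **Post-training INT8 quantization** — per-tensor symmetric weights,
   asymmetric activations calibrated on 200 training segments, int32
   biases, fixed-point requantization multipliers
   `M = m0·2⁻³¹·2⁻ⁿ`; exported as a portable container or an
   xxd-style C header (`model.h`).
7. **Integer-only inference** — int8 tensors, int32 accumulators,
   integer argmax classification (softmax never runs on the label
   path), plus Flash/SRAM footprint accounting under a two-buffer
   ping-pong schedule.
8. **AAMI-style evaluation** — 3×3 confusion matrices, per-class and
   support-weighted precision/recall/F1 (`M_w = Σnᵢ·Mᵢ / Σnᵢ`),
   one-vs-rest AUC, stratified 60/20/20 splits and five-fold
   cross-validation, and float-vs-INT8 agreement reports.

## Worked example

`examples/train_and_quantize.py` runs the core loop — synthesize,
filter, segment, train, quantize, compare:

```
training beats: 3000, test beats: 600
trainable parameters: 251,843
trained for 32 epochs (early stopping), final val accuracy 1.0000
INT8 weight payload = 25% of float32 (75% smaller)
float accuracy 1.0000 | int8 accuracy 1.0000 | delta +0.00 pp
argmax agreement 1.0000, probability R^2 1.0000
flash 247.3 KB, peak SRAM 7.6 KB
```

The delta line is the quantization cost in accuracy percentage points;
argmax agreement and the pooled-probability R² quantify how faithfully
the integer model reproduces the float model's decisions.  The synthetic
classes are cleanly separable by construction, so accuracies sit at the
ceiling — the point of the example is the *agreement* between the two
arithmetic paths and the exact 75% payload reduction, not the absolute
accuracy.  `examples/simulate_and_detect.py` scores the Pan–Tompkins
detector against generator ground truth (sensitivity and positive
predictivity 1.000 at ±50 ms on a 60-beat record at the default noise
level), and `examples/crossval_metrics.py` prints a five-fold
cross-validation summary.

A thin CLI wraps the same stages:

```bash
tinybeat simulate --out run --seed 1
tinybeat segment --out run --seed 1
tinybeat train --out run --seed 1
tinybeat quantize --out run --seed 1     # writes model.tb and model.h
tinybeat evaluate --out run --seed 1
tinybeat footprint --out run --seed 1
```

## Limitations

The synthetic generator provides class-separable morphology with exact
ground truth — it is a test harness, not a patient simulator.  Splits
are beat-wise (a record's beats can appear on both sides of a split),
matching common benchmark practice; a patient-wise splitter
(`patient_wise_split`) is provided for leakage-free protocols.  See
`docs/methods.md` for the full model description and design rationale.
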