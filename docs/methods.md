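# Methods

This note documents the models, algorithms and numerical choices behind
`tinybeat`, in the order the pipeline executes them, together with the
design decisions that were genuinely open and the limitations a user
should keep in mind.

## Problem setting

The task is per-heartbeat classification of single-lead ECG at 360 Hz
into three classes — Normal (N), Ventricular ectopic (V) and
Supraventricular ectopic (S) — under the constraints of
microcontroller-class deployment: kilobyte-scale memory and no
floating-point unit.  The unit of analysis is a 250-sample window
centred on the R peak (125 samples either side, ≈0.694 s at 360 Hz),
which covers the full QRS complex plus the adjacent P and T waves.
Beat symbols from annotation files are grouped by conduction origin:
{N, L, R, e, j} → N, {A, a, J, S} → S, {V, E} → V; fusion, paced,
unknown and non-beat marks are excluded from training and evaluation
(the grouping is exposed as a config override).

## Synthetic data generator

Each beat is a sum of Gaussian bumps (P, Q, R, S, T) on a time axis
relative to the R apex; the templates are:

| class | morphology |
|---|---|
| N | full PQRST, narrow QRS (FWHM ≈ 25 ms) |
| V | wide biphasic complex of two merged bumps (σ = 20 ms and 42 ms, FWHM ≈ 128 ms ≥ the 120 ms wide-complex criterion), no P wave, discordant (inverted) T, coupling shortened 15% |
| S | narrow QRS as N, absent P wave, coupling shortened 25% (premature supraventricular timing) |

Beat-to-beat variability is ~5% multiplicative jitter on amplitudes and
widths.  Records place beats at RR intervals drawn from a mean heart
rate (default 72 beats/min) with ±8% uniform jitter, then add three
noise terms chosen to straddle the analysis band: baseline wander
(0.10 mV at 0.3 Hz, below the 0.5 Hz filter corner), powerline
interference (0.05 mV at 60 Hz, above the 40 Hz corner) and white noise
(SD 0.02 mV).  The V template is deliberately built from two *narrow*
merged bumps rather than one wide Gaussian: real wide-complex beats
retain steep edges, and a single smooth Gaussian of equivalent width
has so little derivative energy that any energy-based QRS detector
would be entitled to miss it.

Ground truth (R-apex sample and class of every beat) is exact by
construction, and one seeded generator drives all randomness per
record.  **What passing tests on this data do and do not show**: the
three classes are separable by design, so classifier accuracies near
1.0 demonstrate that the pipeline's machinery (segmentation, training,
quantization, integer arithmetic) is correct — they say nothing about
performance on clinical recordings, inter-patient variability,
electrode artefacts or rhythms outside the three-class scheme.

## Preprocessing

A fourth-order Butterworth band-pass (0.5–40 Hz) is designed as a
second-order low-pass prototype transformed to band-pass and realised
in cascaded second-order sections (stable at the 0.5 Hz corner).  It is
applied forward-backward, so the net phase is zero (waveform landmarks
do not move) and the effective magnitude response is the square of the
single-pass response; edges use even extension with padding length
3·(order+1).  Normalization is per-segment min–max to [0, 1]; flat
segments (max = min) are dropped and counted rather than zero-filled,
since they carry no morphology and their normalization is undefined.
The pipeline order is filter → segment → normalize, because the
normalization is defined per individual heartbeat window.

## R-peak detection

The detector is the classic energy chain on the already-filtered
signal: five-point derivative (1/8)[−1, −2, 0, 2, 1] scaled by fs/8,
squaring, 150 ms moving-window integration, then an adaptive threshold
over integration-signal peaks with running estimates

    spk ← 0.125·peak + 0.875·spk   (accepted peaks)
    npk ← 0.125·peak + 0.875·npk   (rejected peaks)
    threshold = npk + 0.25·(spk − npk)

initialised from the first two seconds (spk = max, npk = mean/2), with
a 200 ms refractory period.  No search-back second-threshold stage is
implemented.  Accepted detections are refined to the local maximum of
the filtered signal within ±100 ms, so the stored index is the R apex,
consistent with window centring.  All constants are config keys.

Training datasets centre windows on annotation indices (benchmark
practice); the detector drives the unlabelled inference path.  Both
modes are provided because either convention is defensible.

## Classifier

Canonical topology (input 250×1): Conv1D(16, k=3, ReLU) → (248, 16) →
MaxPool(2) → (124, 16) → Conv1D(32, k=3, ReLU) → (122, 32) → Flatten →
3904 → Dense(64, ReLU) → Dense(3, softmax).  Convolutions are valid
(no padding), stride 1.  Batch normalization follows each convolution
and 20% dropout precedes the output layer; both are on by default and
toggleable.  The measured trainable parameter count is 251,843,
dominated by the 3904→64 dense layer (249,920) — a consequence of
flattening 122×32 channels straight into a dense head.  A `reduced`
preset (extra MaxPool(2) after conv2, 9-unit dense head) exists for
genuinely kilobyte-scale deployments; it is never selected silently.

Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch 32, categorical
cross-entropy, up to 100 epochs with early stopping on validation loss
(patience 10) and best-weight restoration.  Weights are initialised
Glorot-uniform (bounds √(6/(fan_in+fan_out))) from a seeded generator;
with a fixed seed training is bit-reproducible (single-threaded NumPy).
The implementation is pure NumPy (im2col convolutions, analytic
backward passes, verified against numerical differentiation) so that
every tensor the quantizer consumes is directly inspectable.

## Quantization

Batch normalization is first folded into the preceding convolution
(w′ = w·γ/√(σ²+ε), b′ = (b−μ)·γ/√(σ²+ε)+β), giving the inference graph
conv→pool→conv→flatten→dense→dense.  Then:

* **weights**: per-tensor symmetric int8, scale = max(|min|,|max|)/127,
  zero point 0 (per-channel left as future work);
* **activations**: per-tensor asymmetric int8 over the calibrated
  range, widened to contain 0 so zero is exactly representable;
  calibration records running min/max over a 200-segment seeded
  subsample of the training data;
* **biases**: int32 at scale s_in·s_w;
* **requantization**: M = s_in·s_w/s_out decomposed as m0·2⁻³¹·2⁻ⁿ with
  m0 ∈ [2³⁰, 2³¹), accurate to better than 2⁻²⁴ relative.

Value rounding is half-away-from-zero everywhere.  The zero point is
the one exception: it uses round-half-to-even, so a perfectly symmetric
activation range maps to zero point 0 instead of −1 (the half-even
convention standard in integer inference runtimes).  Quantized weight
payload is exactly 25% of the float32 payload (1 byte vs 4 per
element); total serialized size adds int32 biases and a JSON metadata
header.  The portable container round-trips bit-identically and the
same bytes are embedded in the generated `model.h`.

## Integer inference engine

For conv and dense layers the engine computes
`acc = Σ(q_in − zp_in)·q_w + bias` in int32, requantizes with the
fixed-point multiplier and adds zp_out, clamping to [−128, 127]; ReLU
is fused as a clamp floor at zp_out.  Max pooling operates directly on
int8 codes (order-preserving, so quantization parameters pass through
unchanged).  Requantization uses the 64-bit high word of acc×m0 — the
standard hardware idiom — while accumulators remain int32; there is no
int64 accumulation path.  Classification is integer argmax over the
final int8 logits: softmax is monotone, so it never runs on the label
path.  Probabilities, when requested, are a display feature computed by
dequantizing the logits (explicitly floating point).  A trace mode
records every intermediate tensor so tests can assert the label path is
integer-only.

Footprint accounting: Flash = serialized payload bytes; SRAM = the peak
over ops of input buffer + output buffer (int8 at 1 byte/element) plus
one int32 accumulator row per output tile, under a two-buffer ping-pong
schedule with no operator fusion beyond ReLU.  For the canonical
topology this measures ≈247 KB Flash / ≈7.6 KB SRAM — the honest cost
of the 3904-wide flatten; the `reduced` preset is the route to
tens-of-KB budgets.

## Evaluation

Metrics come from the 3×3 confusion matrix (rows true, columns
predicted, order N, V, S): accuracy = trace/total; per-class
precision/recall/F1 one-vs-rest; multiclass summaries by support
weighting M_w = Σnᵢ·Mᵢ/Σnᵢ (macro averages are reported alongside,
since with equal supports the two coincide).  Zero-denominator metrics
are reported as 0 with an explicit flag; zero-support classes are
excluded from weighting with a warning.  AUC is one-vs-rest via the
rank statistic, support-weighted the same way.  Splits (60/20/20) and
five-fold cross-validation are stratified at the beat level — the
benchmark convention, which permits beats of one record on both sides
of a split; `patient_wise_split` offers the leakage-free alternative.
Float-vs-INT8 agreement reports accuracy delta in percentage points,
argmax agreement fraction, and the squared Pearson correlation of
pooled class probabilities (the scatter-plot R² convention).

## Problem sizes and tolerances

The study conditions used throughout tests and the acceptance script
are 3,000 training beats (10 records × 300 beats, equal N/V/S mix,
default noise) and 600 held-out test beats from unseen records; the
quantization calibration uses 200 segments.  Cross-validation tests use
a shortened schedule (10 epochs, patience 4), sufficient on this data
where validation accuracy saturates within a few epochs.  Numerical
tolerances: integer kernels are checked within one output scale of a
float oracle on dequantized tensors; filter linearity to 1e-9 relative;
normalization round-trip to 1e-12.  Ties in integer argmax resolve to
the first (lowest-index) class; ties in max pooling to either operand
(values equal).

## Known limitations

* The generator does not model rhythm context (no compensatory pauses,
  bigeminy, or rate-dependent morphology), electrode motion artefacts,
  or any class outside N/V/S.
* Per-tensor weight quantization is coarser than per-channel; on models
  with wide per-channel weight spread it costs more accuracy.
* Saturating int32 accumulation is assumed never to engage for
  realistically-scaled inputs; extremely large calibration ranges could
  violate this.
* The WFDB layer implements formats 16 and 212 and MIT annotations
  only — enough to read standard arrhythmia-database records and to
  round-trip its own files; exotic formats (8, 80, 310…) are out of
  scope.
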