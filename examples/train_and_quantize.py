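"""Train the compact 1D-CNN, quantize it to INT8 and compare the two.

Builds a ~3,000-beat synthetic training set and a ~600-beat held-out
test set, trains the float model with the default hyperparameters
(Adam, lr 0.001, batch 32, early stopping), converts it to a
full-integer INT8 model via post-training quantization (200-segment
calibration), and reports the float-vs-integer agreement plus the
deployment footprint.
"""

from tinybeat import (
    EcgRecord,
    SynthConfig,
    TrainConfig,
    agreement_report,
    build_dataset,
    build_model,
    calibrate,
    convert,
    count_parameters,
    design_bandpass,
    filter_zero_phase,
    footprint,
    generate_record,
    representative_subsample,
    stratified_split,
    train,
)
from tinybeat.quantize import float_weight_payload_bytes, weight_payload_bytes

spec = design_bandpass()


def make_dataset(n_records, seed0):
    records = []
    for s in range(n_records):
        rec, _ = generate_record(SynthConfig(n_beats=300, seed=seed0 + s))
        records.append(EcgRecord(
            rec.record_id, filter_zero_phase(rec.signal, spec),
            rec.fs, rec.lead, rec.annotations,
        ))
    return build_dataset(records, mode="annotations", seed=seed0)


train_ds = make_dataset(10, seed0=0)
test_ds = make_dataset(2, seed0=100)
print(f"training beats: {len(train_ds)}, test beats: {len(test_ds)}")

tr, va, _ = stratified_split(train_ds, (0.75, 0.25, 0.0), seed=1)
model = build_model(seed=1)
print(f"trainable parameters: {count_parameters(model):,}")
train(model, tr, va, TrainConfig(seed=1))
print(f"trained for {len(model.history['loss'])} epochs "
      f"(early stopping), final val accuracy {model.history['val_accuracy'][-1]:.4f}")

rep = representative_subsample(tr, 200, seed=2)
qm = convert(model, calibrate(model, rep))
ratio = weight_payload_bytes(qm) / float_weight_payload_bytes(model)
print(f"INT8 weight payload = {ratio:.0%} of float32 ({1 - ratio:.0%} smaller)")

agree = agreement_report(model, qm, test_ds)
print(f"float accuracy {agree.accuracy_float:.4f} | int8 accuracy {agree.accuracy_int8:.4f} "
      f"| delta {agree.delta_pp:+.2f} pp")
print(f"argmax agreement {agree.argmax_agreement:.4f}, probability R^2 {agree.r_squared:.4f}")

fp = footprint(qm)
print(f"flash {fp.flash_bytes / 1024:.1f} KB, peak SRAM {fp.sram_bytes / 1024:.1f} KB")
print("(the integer path never touches floating point; probabilities above are a "
      "display-only dequantization)")
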