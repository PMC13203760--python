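"""Stage-wise pipeline runner with config, seeds and artifact manifests.

``run_pipeline`` wires the stages (simulate, segment, train, quantize,
infer, evaluate, footprint) over a single output directory.  Every stage
writes versioned artifacts plus a JSON manifest entry recording inputs,
outputs, seeds and a hash of the stage parameters, so a rerun with the
same config and seed reproduces identical artifacts.  All randomness is
funnelled through one global seed expanded per stage with
``numpy.random.SeedSequence(seed).spawn`` (stable, documented rule).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cnn, detect, engine, io as ecg_io, metrics, preprocess, quantize, synthetic
from .containers import EcgRecord

logger = logging.getLogger(__name__)

STAGES = ("simulate", "segment", "train", "quantize", "infer", "evaluate", "footprint")


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class RunConfig:
    """All stage parameters with paper-stated defaults where they exist.

    Filter 0.5-40 Hz order 4; 250-sample windows; lr 0.001, batch 32,
    epochs 100, patience 10, dropout 0.2; 60/20/20 split; 5 folds.
    """

    out_dir: str = "tinybeat_run"
    seed: int = 0
    # simulate
    n_records: int = 10
    beats_per_record: int = 300
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    mean_hr: float = 72.0
    # filter
    filter_order: int = 4
    filter_low_hz: float = 0.5
    filter_high_hz: float = 40.0
    # segmentation
    segment_mode: str = "annotations"  # annotations | detected
    # training
    train_cfg: cnn.TrainConfig = field(default_factory=cnn.TrainConfig)
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # quantization
    calibration_segments: int = 200
    # evaluation
    n_folds: int = 5
    log_level: str = "INFO"


def _stage_seeds(seed: int) -> dict[str, int]:
    """Expand the global seed into one sub-seed per stage (all < 2^31)."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))
        for stage, child in zip(STAGES, children)
    }


def _params_hash(cfg: RunConfig) -> str:
    # Hash the scientific parameters only, not artifact location or verbosity.
    payload = {k: v for k, v in dataclasses.asdict(cfg).items()
               if k not in ("out_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages; returns the manifest dict (also on disk).

    Stage dependencies must be satisfiable from earlier stages in the
    same call or from artifacts already in ``cfg.out_dir``; otherwise a
    :class:`DependencyError` names the missing stage.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest_path = out / "manifest.json"
    manifest: dict = {"seed": cfg.seed, "params_hash": _params_hash(cfg), "stages": {}}
    if manifest_path.exists():
        manifest["stages"] = json.loads(manifest_path.read_text()).get("stages", {})

    fspec = preprocess.design_bandpass(
        cfg.filter_order, cfg.filter_low_hz, cfg.filter_high_hz, fs=360.0
    )

    def record_stage(name: str, inputs: list[str], outputs: list[str]) -> None:
        manifest["stages"][name] = {
            "inputs": inputs, "outputs": outputs,
            "seed": seeds[name], "params_hash": _params_hash(cfg),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    def require(path: Path, stage: str) -> Path:
        if not path.exists():
            raise DependencyError(f"missing artifact {path.name}: run stage '{stage}' first")
        return path

    if "simulate" in stages:
        rec_dir = out / "records"
        written = []
        for i in range(cfg.n_records):
            scfg = synthetic.SynthConfig(
                n_beats=cfg.beats_per_record, class_mix=cfg.class_mix,
                mean_hr=cfg.mean_hr, seed=seeds["simulate"] + i,
            )
            rec, _ = synthetic.generate_record(scfg)
            written.append(str(ecg_io.write_wfdb_record(rec, rec_dir)))
        record_stage("simulate", [], written)

    if "segment" in stages:
        rec_dir = require(out / "records", "simulate")
        records = []
        for hea in sorted(rec_dir.glob("*.hea")):
            rec = ecg_io.read_wfdb_record(hea)
            records.append(EcgRecord(
                rec.record_id, preprocess.filter_zero_phase(rec.signal, fspec),
                rec.fs, rec.lead, rec.annotations,
            ))
        ds = detect.build_dataset(
            records, mode=cfg.segment_mode, seed=seeds["segment"]
        )
        ecg_io.save_dataset(ds, out / "beats.npz")
        record_stage("segment", [str(rec_dir)], [str(out / "beats.npz")])

    if "train" in stages:
        ds = ecg_io.load_dataset(require(out / "beats.npz", "segment"))
        tr, va, te = metrics.stratified_split(ds, cfg.split_fractions, seed=seeds["train"])
        model = cnn.build_model(seed=seeds["train"])
        tcfg = cnn.TrainConfig(**{**cfg.train_cfg.__dict__, "seed": seeds["train"]})
        cnn.train(model, tr, va, tcfg)
        cnn.save_float_model(model, out / "model_float.npz")
        ecg_io.save_dataset(te, out / "beats_test.npz")
        hist = model.history
        csv = "epoch," + ",".join(hist) + "\n" + "\n".join(
            f"{i}," + ",".join(f"{hist[k][i]:.6f}" for k in hist)
            for i in range(len(hist["loss"]))
        )
        (out / "history.csv").write_text(csv + "\n")
        record_stage("train", [str(out / "beats.npz")],
                     [str(out / "model_float.npz"), str(out / "beats_test.npz")])

    if "quantize" in stages:
        model = cnn.load_float_model(require(out / "model_float.npz", "train"))
        ds = ecg_io.load_dataset(require(out / "beats.npz", "segment"))
        rep = quantize.representative_subsample(
            ds, cfg.calibration_segments, seed=seeds["quantize"]
        )
        qm = quantize.convert(model, quantize.calibrate(model, rep))
        quantize.export_portable(qm, out / "model.tb")
        (out / "model.h").write_text(quantize.export_c_header(qm))
        record_stage("quantize", [str(out / "model_float.npz")],
                     [str(out / "model.tb"), str(out / "model.h")])

    if "infer" in stages:
        qm = quantize.load_portable(require(out / "model.tb", "quantize"))
        te = ecg_io.load_dataset(require(out / "beats_test.npz", "train"))
        labels, probs = engine.predict_int8(qm, te.X, probabilities=True)
        rows = ["index,label,p_N,p_V,p_S"] + [
            f"{i},{l.name}," + ",".join(f"{p:.6f}" for p in probs[i])
            for i, l in enumerate(labels)
        ]
        (out / "predictions.csv").write_text("\n".join(rows) + "\n")
        record_stage("infer", [str(out / "model.tb")], [str(out / "predictions.csv")])

    if "evaluate" in stages:
        model = cnn.load_float_model(require(out / "model_float.npz", "train"))
        qm = quantize.load_portable(require(out / "model.tb", "quantize"))
        te = ecg_io.load_dataset(require(out / "beats_test.npz", "train"))
        probs = cnn.predict_float(model, te.X)
        report = metrics.evaluate_predictions(te.y, probs.argmax(axis=1), probs)
        agree = metrics.agreement_report(model, qm, te)
        payload = {
            "float": {
                "accuracy": report.accuracy,
                "weighted": report.weighted,
                "macro": report.macro,
                "auc": report.auc,
                "confusion": report.confusion.tolist(),
            },
            "agreement": dataclasses.asdict(agree),
        }
        (out / "evaluation.json").write_text(json.dumps(payload, indent=2))
        record_stage("evaluate", [str(out / "model_float.npz"), str(out / "model.tb")],
                     [str(out / "evaluation.json")])

    if "footprint" in stages:
        qm = quantize.load_portable(require(out / "model.tb", "quantize"))
        fp = engine.footprint(qm)
        (out / "footprint.json").write_text(json.dumps(dataclasses.asdict(fp), indent=2))
        record_stage("footprint", [str(out / "model.tb")], [str(out / "footprint.json")])

    return manifest
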