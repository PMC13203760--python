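"""Shared fixtures: synthetic datasets and one trained/quantized model.

The heavy artifacts (a 3,000-beat training dataset, a 600-beat test set,
a model trained with the default hyperparameters and its INT8
conversion) are session-scoped so the whole suite trains exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tinybeat.cnn import TrainConfig, build_model, train
from tinybeat.containers import EcgRecord
from tinybeat.detect import build_dataset
from tinybeat.preprocess import design_bandpass, filter_zero_phase
from tinybeat.quantize import calibrate, convert, representative_subsample
from tinybeat.metrics import stratified_split
from tinybeat.synthetic import SynthConfig, generate_record

FILTER_SPEC = design_bandpass()


def make_beat_dataset(n_records: int, beats_per_record: int, seed0: int):
    """Generate, filter and segment synthetic records into a dataset."""
    records = []
    for s in range(n_records):
        rec, _ = generate_record(SynthConfig(n_beats=beats_per_record, seed=seed0 + s))
        records.append(EcgRecord(
            rec.record_id, filter_zero_phase(rec.signal, FILTER_SPEC),
            rec.fs, rec.lead, rec.annotations,
        ))
    return build_dataset(records, mode="annotations", seed=seed0)


@pytest.fixture(scope="session")
def train_dataset():
    """~3,000 beats, equal N/V/S mix."""
    return make_beat_dataset(10, 300, seed0=0)


@pytest.fixture(scope="session")
def test_dataset():
    """~600 held-out beats from records the model never saw."""
    return make_beat_dataset(2, 300, seed0=100)


@pytest.fixture(scope="session")
def trained_model(train_dataset):
    """Model trained with the default hyperparameters (early stopping)."""
    tr, va, _ = stratified_split(train_dataset, (0.75, 0.25, 0.0), seed=1)
    model = build_model(seed=1)
    train(model, tr, va, TrainConfig(seed=1))
    model._fixture_train_part = tr  # reused for calibration
    return model


@pytest.fixture(scope="session")
def quant_model(trained_model):
    """INT8 conversion calibrated on 200 training segments (seed 2)."""
    rep = representative_subsample(trained_model._fixture_train_part, 200, seed=2)
    return convert(trained_model, calibrate(trained_model, rep))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
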