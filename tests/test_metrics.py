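"""Metrics engine vs brute-force oracles; splits and cross-validation."""

import numpy as np
import pytest

from tinybeat.containers import BeatDataset
from tinybeat.metrics import (
    auc_ovr,
    confusion,
    evaluate_predictions,
    metrics_from_confusion,
    patient_wise_split,
    stratified_split,
)


def brute_force_counts(y_true, y_pred, cls):
    """Direct recount of TP/TN/FP/FN for one class, one-vs-rest."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
    tn = len(y_true) - tp - fp - fn
    return tp, tn, fp, fn


def brute_force_auc(y_bin, scores):
    """Pairwise-comparison rank statistic over all positive/negative pairs."""
    pos = [s for y, s in zip(y_bin, scores) if y]
    neg = [s for y, s in zip(y_bin, scores) if not y]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_confusion_hand_count():
    cm = confusion([0, 0, 1], [0, 1, 1])
    np.testing.assert_array_equal(cm, [[1, 1, 0], [0, 1, 0], [0, 0, 0]])


def test_confusion_perfect_is_diagonal(rng):
    y = rng.integers(0, 3, 50)
    cm = confusion(y, y)
    assert np.trace(cm) == 50 and cm.sum() == 50


def test_confusion_rejects_empty_and_alien_labels():
    with pytest.raises(ValueError):
        confusion([], [])
    with pytest.raises(ValueError):
        confusion([0, 3], [0, 0])


def test_metrics_binary_style_case():
    # TP=3, FP=1, FN=2 for class N, remainder true negatives.
    y_true = [0] * 5 + [1] * 3
    y_pred = [0, 0, 0, 1, 1] + [0, 1, 1]
    report = metrics_from_confusion(confusion(y_true, y_pred))
    n = report.per_class["N"]
    assert n["precision"] == pytest.approx(0.75)
    assert n["recall"] == pytest.approx(0.6)
    assert n["f1"] == pytest.approx(2 * 0.75 * 0.6 / 1.35)


def test_weighted_average_closed_form():
    # class metrics (1.0, 0.5, 0.0) with supports (2, 1, 1) -> 0.625
    m = np.array([1.0, 0.5, 0.0])
    n = np.array([2, 1, 1])
    assert float((n * m).sum() / n.sum()) == pytest.approx(0.625)
    # ... and with equal supports the weighted average is the macro mean
    y_true = [0, 0, 1, 1, 2, 2]
    y_pred = [0, 1, 1, 2, 2, 0]
    report = metrics_from_confusion(confusion(y_true, y_pred))
    for key in ("precision", "recall", "f1"):
        assert report.weighted[key] == pytest.approx(report.macro[key])


def test_identity_confusion_all_ones():
    report = metrics_from_confusion(np.diag([5, 4, 3]))
    assert report.accuracy == 1.0
    assert report.weighted["f1"] == 1.0
    assert not report.flags


def test_zero_denominator_flagged():
    # nothing predicted as V -> precision undefined, reported 0 + flag
    report = metrics_from_confusion(confusion([0, 1, 2], [0, 0, 2]))
    assert report.per_class["V"]["precision"] == 0.0
    assert any("precision[V]" in f for f in report.flags)


@pytest.mark.parametrize("case", range(100))
def test_metrics_match_brute_force_recount(case):
    rng = np.random.default_rng(case)
    n = int(rng.integers(3, 30))
    y_true = rng.integers(0, 3, n)
    y_pred = rng.integers(0, 3, n)
    report = metrics_from_confusion(confusion(y_true, y_pred))
    assert report.accuracy == pytest.approx(np.mean(y_true == y_pred))
    for i, cls in enumerate("NVS"):
        tp, tn, fp, fn = brute_force_counts(list(y_true), list(y_pred), i)
        pc = report.per_class[cls]
        assert pc["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
        assert pc["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)


def test_auc_perfect_and_tied():
    y = np.array([0, 0, 1, 1, 2, 2])
    perfect = np.eye(3)[y]
    assert auc_ovr(y, perfect) == pytest.approx(1.0)
    tied = np.full((6, 3), 1 / 3)
    assert auc_ovr(y, tied) == pytest.approx(0.5)


def test_auc_small_case_matches_pairwise_oracle():
    y = np.array([0, 1, 0, 2, 1, 0])
    rng = np.random.default_rng(3)
    probs = rng.random((6, 3))
    probs /= probs.sum(axis=1, keepdims=True)
    expected = np.average(
        [brute_force_auc(y == i, probs[:, i]) for i in range(3)],
        weights=[(y == i).sum() for i in range(3)],
    )
    assert auc_ovr(y, probs) == pytest.approx(expected)


@pytest.mark.parametrize("case", range(20))
def test_auc_matches_pairwise_oracle_random(case):
    rng = np.random.default_rng(1000 + case)
    n = int(rng.integers(6, 25))
    y = rng.integers(0, 3, n)
    while len(set(y.tolist())) < 2:
        y = rng.integers(0, 3, n)
    probs = rng.random((n, 3))
    probs /= probs.sum(axis=1, keepdims=True)
    present = [i for i in range(3) if (y == i).any() and not (y == i).all()]
    expected = np.average(
        [brute_force_auc(y == i, probs[:, i]) for i in present],
        weights=[(y == i).sum() for i in present],
    )
    assert auc_ovr(y, probs) == pytest.approx(expected)


def _balanced_dataset(per_class=100, seed=0):
    n = per_class * 3
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(3), per_class)
    return BeatDataset(
        X=rng.random((n, 250)), y=y, r_index=np.arange(n),
        record_id=[f"r{i % 7}" for i in range(n)], seed=seed,
    )


def test_stratified_split_proportions():
    ds = _balanced_dataset(100)
    tr, va, te = stratified_split(ds, (0.6, 0.2, 0.2), seed=1)
    for part, frac in ((tr, 0.6), (va, 0.2), (te, 0.2)):
        for c, cnt in part.class_counts.items():
            assert cnt == int(100 * frac)
    assert len(tr) + len(va) + len(te) == len(ds)


def test_stratified_split_deterministic_and_disjoint():
    ds = _balanced_dataset(40)
    a = stratified_split(ds, seed=5)
    b = stratified_split(ds, seed=5)
    for pa, pb in zip(a, b):
        np.testing.assert_array_equal(pa.r_index, pb.r_index)
    # r_index doubles as a unique beat id here: multiset union == input
    union = np.sort(np.concatenate([p.r_index for p in a]))
    np.testing.assert_array_equal(union, np.sort(ds.r_index))


def test_stratified_split_small_class_rejected():
    ds = _balanced_dataset(100)
    tiny = ds.subset(np.concatenate([np.arange(100), np.arange(100, 103)]))
    with pytest.raises(ValueError):
        stratified_split(tiny)


def test_patient_wise_split_no_record_overlap():
    ds = _balanced_dataset(60)
    parts = patient_wise_split(ds, seed=2)
    sets = [set(p.record_id) for p in parts]
    assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])
    assert sum(len(p) for p in parts) == len(ds)


def test_evaluate_predictions_includes_auc(rng):
    y = rng.integers(0, 3, 60)
    probs = np.eye(3)[y] * 0.8 + 0.2 / 3
    report = evaluate_predictions(y, probs.argmax(axis=1), probs)
    assert report.auc == pytest.approx(1.0)
    assert report.accuracy == 1.0
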