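"""AAMI-style evaluation: confusion matrices, weighted metrics, splits,
five-fold cross-validation and float-vs-INT8 agreement.

Per-class metrics are one-vs-rest on the 3x3 confusion matrix (rows =
true, columns = predicted, order N, V, S):

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Multiclass summaries use the support-weighted average
``M_weighted = sum(n_i * M_i) / sum(n_i)`` (macro averages are reported
alongside).  AUC is one-vs-rest via the rank statistic, weighted the
same way.  Splits and folds are stratified at the beat level — as in
benchmark practice, without inter-patient separation (a known source of
optimistic bias; a patient-wise splitter is provided separately).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .cnn import FloatModel, TrainConfig, build_model, predict_float, train
from .containers import BeatDataset, CLASS_ALPHABET, N_CLASSES
from .engine import predict_int8
from .quantize import QuantModel, calibrate, convert, representative_subsample

logger = logging.getLogger(__name__)


@dataclass
class MetricReport:
    """Confusion counts plus derived metrics (all in [0, 1])."""

    confusion: np.ndarray  # (3, 3) int
    accuracy: float
    per_class: dict[str, dict[str, float]]  # class -> {precision, recall, f1, support}
    weighted: dict[str, float]
    macro: dict[str, float]
    auc: float | None = None
    flags: list[str] = field(default_factory=list)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """3x3 confusion counts, rows = true, cols = predicted (N, V, S)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("cannot build a confusion matrix from no labels")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, range(N_CLASSES)).all():
            raise ValueError(f"{name} contains labels outside the (N, V, S) alphabet")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> MetricReport:
    """Derive accuracy and per-class one-vs-rest precision/recall/F1.

    Zero-denominator metrics are reported as 0 with a flag; classes with
    zero support are excluded from the weighted average with a warning.
    """
    cm = np.asarray(cm, dtype=np.int64)
    total = int(cm.sum())
    if total <= 0:
        raise ValueError("empty confusion matrix")
    accuracy = float(np.trace(cm)) / total
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}
    supports, precs, recs, f1s = [], [], [], []
    for i, cls in enumerate(CLASS_ALPHABET):
        tp = int(cm[i, i])
        fp = int(cm[:, i].sum()) - tp
        fn = int(cm[i, :].sum()) - tp
        support = tp + fn
        def safe(num, den, name):
            if den == 0:
                flags.append(f"{name}[{cls.name}] has zero denominator; reported as 0")
                return 0.0
            return num / den
        precision = safe(tp, tp + fp, "precision")
        recall = safe(tp, tp + fn, "recall")
        f1 = safe(2 * precision * recall, precision + recall, "f1")
        per_class[cls.name] = {
            "precision": precision, "recall": recall, "f1": f1, "support": support,
        }
        if support > 0:
            supports.append(support)
            precs.append(precision)
            recs.append(recall)
            f1s.append(f1)
        else:
            logger.warning("class %s has zero support; excluded from weighting", cls.name)
    w = np.asarray(supports, dtype=np.float64)
    weighted = {
        "precision": float(np.average(precs, weights=w)),
        "recall": float(np.average(recs, weights=w)),
        "f1": float(np.average(f1s, weights=w)),
    }
    macro = {
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "f1": float(np.mean(f1s)),
    }
    return MetricReport(
        confusion=cm, accuracy=accuracy, per_class=per_class,
        weighted=weighted, macro=macro, flags=flags,
    )


def auc_ovr(y_true: np.ndarray, probabilities: np.ndarray) -> float:
    """Support-weighted one-vs-rest AUC from the rank statistic."""
    y_true = np.asarray(y_true, dtype=np.int64)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    aucs, supports = [], []
    for i in range(N_CLASSES):
        pos = y_true == i
        if not pos.any() or pos.all():
            logger.warning("class %s absent (or universal); excluded from AUC", CLASS_ALPHABET[i].name)
            continue
        aucs.append(roc_auc_score(pos.astype(int), probabilities[:, i]))
        supports.append(int(pos.sum()))
    if not aucs:
        raise ValueError("AUC undefined: need at least one class with both labels present")
    return float(np.average(aucs, weights=np.asarray(supports, dtype=np.float64)))


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, probabilities: np.ndarray | None = None
) -> MetricReport:
    """Full metric report from labels (and optionally probabilities)."""
    report = metrics_from_confusion(confusion(y_true, y_pred))
    if probabilities is not None:
        report.auc = auc_ovr(y_true, probabilities)
    return report


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def stratified_split(
    ds: BeatDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[BeatDataset, BeatDataset, BeatDataset]:
    """Beat-wise stratified train/validation/test split.

    Per-class proportions are preserved within rounding; the three parts
    are disjoint and their union is the input.  Requires >= 5 beats per
    class.  Beat-wise means segments of one subject can land in several
    parts — matching benchmark practice, not a patient-wise protocol.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for c in range(N_CLASSES):
        idx = np.flatnonzero(ds.y == c)
        if idx.size < 5:
            raise ValueError(f"class {CLASS_ALPHABET[c].name} has only {idx.size} beats (< 5)")
        idx = rng.permutation(idx)
        n_train = int(round(fractions[0] * idx.size))
        n_val = int(round(fractions[1] * idx.size))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(ds.subset(np.sort(np.asarray(p, dtype=np.int64))) for p in parts)


def patient_wise_split(
    ds: BeatDataset, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> tuple[BeatDataset, BeatDataset, BeatDataset]:
    """Record-level split (no subject appears in two parts).

    Stricter than the benchmark protocol; class balance is not
    guaranteed.  Provided for leakage-free experiments.
    """
    records = sorted(set(ds.record_id))
    if len(records) < 3:
        raise ValueError("need at least 3 distinct records for a patient-wise split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = max(1, int(round(fractions[0] * len(records))))
    n_val = max(1, int(round(fractions[1] * len(records))))
    groups = [
        {records[i] for i in order[:n_train]},
        {records[i] for i in order[n_train : n_train + n_val]},
        {records[i] for i in order[n_train + n_val :]},
    ]
    rid = np.asarray(ds.record_id)
    return tuple(
        ds.subset(np.flatnonzero(np.isin(rid, sorted(g)))) for g in groups
    )


# ---------------------------------------------------------------------------
# Cross-validation and agreement
# ---------------------------------------------------------------------------

def _summarize(reports: list[MetricReport]) -> dict[str, tuple[float, float]]:
    rows = {
        "accuracy": [r.accuracy for r in reports],
        "precision": [r.weighted["precision"] for r in reports],
        "recall": [r.weighted["recall"] for r in reports],
        "f1": [r.weighted["f1"] for r in reports],
    }
    if all(r.auc is not None for r in reports):
        rows["auc"] = [r.auc for r in reports]
    return {k: (float(np.mean(v)), float(np.std(v))) for k, v in rows.items()}


def crossval_5fold(
    ds: BeatDataset,
    train_cfg: TrainConfig | None = None,
    quantized: bool = False,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[list[MetricReport], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation (default 5 folds).

    Each fold trains a fresh model on the other folds (a slice of the
    training part doubles as the early-stopping validation set) and
    scores the held-out fold; with ``quantized=True`` the fold model is
    INT8-converted and scored on the integer path.  Returns per-fold
    reports and a mean/SD summary per metric.
    """
    train_cfg = train_cfg or TrainConfig()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports: list[MetricReport] = []
    for fold, (fit_idx, test_idx) in enumerate(skf.split(ds.X, ds.y)):
        fit = ds.subset(fit_idx)
        test = ds.subset(test_idx)
        tr, va, _ = stratified_split(fit, (0.75, 0.25, 0.0), seed=seed + fold)
        model = build_model(seed=seed + fold)
        cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed + fold})
        train(model, tr, va, cfg)
        if quantized:
            qm = convert(model, calibrate(model, representative_subsample(tr, seed=seed + fold)))
            labels, probs = predict_int8(qm, test.X, probabilities=True)
            y_pred = np.array([int(l) for l in labels])
        else:
            probs = predict_float(model, test.X)
            y_pred = probs.argmax(axis=1)
        reports.append(evaluate_predictions(test.y, y_pred, probs))
        logger.info("fold %d: accuracy %.4f", fold, reports[-1].accuracy)
    return reports, _summarize(reports)


@dataclass
class AgreementReport:
    """Float-vs-INT8 comparison on one test set."""

    accuracy_float: float
    accuracy_int8: float
    delta_pp: float  # accuracy_float - accuracy_int8, percentage points
    r_squared: float  # squared Pearson correlation of pooled probabilities
    argmax_agreement: float
    n: int


def agreement_report(model: FloatModel, qm: QuantModel, test: BeatDataset) -> AgreementReport:
    """Compare a float model against its quantized version on a test set."""
    if qm.alphabet != "NVS" or qm.input_length != model.architecture.input_length:
        raise ValueError("float and quantized models disagree on alphabet or input shape")
    probs_f = predict_float(model, test.X)
    labels_q, probs_q = predict_int8(qm, test.X, probabilities=True)
    y_pred_f = probs_f.argmax(axis=1)
    y_pred_q = np.array([int(l) for l in labels_q])
    acc_f = float((y_pred_f == test.y).mean())
    acc_q = float((y_pred_q == test.y).mean())
    r = np.corrcoef(probs_f.ravel(), probs_q.ravel())[0, 1]
    return AgreementReport(
        accuracy_float=acc_f,
        accuracy_int8=acc_q,
        delta_pp=(acc_f - acc_q) * 100.0,
        r_squared=float(r ** 2),
        argmax_agreement=float((y_pred_f == y_pred_q).mean()),
        n=len(test),
    )
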