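"""Training, cross-validation, confusion-matrix metrics, patient alerting.

Evaluation follows the screening protocol: segment-level confusion matrices
with per-class accuracy/precision/recall/F1

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

each computed treating one class as positive, plus a patient-level roll-up:
a recording is flagged anomalous as soon as one of its segments is predicted
anomalous, so patient-level recall is always at least the segment-level
anomalous recall.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, make_folds
from .model import (
    ANOMALOUS_INDEX,
    NORMAL_INDEX,
    ModelConfig,
    SegmentClassifier,
    build_model,
    label_from_proba,
)
from .nn import Adam, cross_entropy
from .segmenter import ANOMALOUS, NORMAL, SegmentDataset

CLASSES = (NORMAL, ANOMALOUS)


class EvalError(Exception):
    pass


def round2(x: float) -> float:
    """Round half-up to 2 decimals (matches the reported tables)."""
    return float(decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
    ))


@dataclass
class TrainConfig:
    epochs: int = 200
    val_fraction: float = 0.3
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    k: int = 10

    def __post_init__(self):
        if self.epochs < 1:
            raise EvalError("epochs must be >= 1")
        if not 0 < self.val_fraction < 1:
            raise EvalError("val_fraction must be in (0, 1)")
        if self.optimizer != "adam":
            raise EvalError("only the adam optimizer is supported")


@dataclass
class TrainHistory:
    """Per-epoch learning curves; accuracies in percent."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "train_acc": self.train_accuracy,
                "val_acc": self.val_accuracy,
            }
        )


@dataclass
class ConfusionMatrix:
    """2x2 true-by-predicted counts in (normal, anomalous) order."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise EvalError("confusion matrix must be 2x2 with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_counts(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) treating ``class_index`` as the positive class."""
        other = 1 - class_index
        tp = int(self.counts[class_index, class_index])
        tn = int(self.counts[other, other])
        fp = int(self.counts[other, class_index])
        fn = int(self.counts[class_index, other])
        return tp, tn, fp, fn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count (true, predicted) pairs; labels are 'normal'/'anomalous' or 0/1."""
    t = _as_index(true_labels)
    p = _as_index(predicted_labels)
    if len(t) != len(p):
        raise EvalError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def _as_index(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iub":
        idx = arr.astype(np.int64)
        if idx.size and not np.isin(idx, [0, 1]).all():
            raise EvalError("integer labels must be 0 (normal) or 1 (anomalous)")
        return idx
    mapping = {NORMAL: 0, "N": 0, ANOMALOUS: 1, "A": 1}
    try:
        return np.array([mapping[str(v)] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise EvalError(f"label outside {{normal, anomalous}}: {exc}") from exc


def metrics(matrix: ConfusionMatrix) -> dict:
    """Per-class accuracy/precision/recall/F1 (percent) plus overall accuracy.

    A metric whose denominator is zero (no true or no predicted members of
    a class) is reported as ``None`` — never silently 0.  Values are full
    precision; use :func:`report` for the rounded table form.
    """
    if matrix.total == 0:
        raise EvalError("confusion matrix is empty")
    out: dict = {"per_class": {}, "overall_accuracy": 100.0 * np.trace(matrix.counts) / matrix.total}
    for idx, name in enumerate(CLASSES):
        tp, tn, fp, fn = matrix.class_counts(idx)
        precision = 100.0 * tp / (tp + fp) if tp + fp else None
        recall = 100.0 * tp / (tp + fn) if tp + fn else None
        f1 = 100.0 * 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else None
        out["per_class"][name] = {
            "accuracy": 100.0 * (tp + tn) / matrix.total,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    return out


def report(matrix: ConfusionMatrix) -> dict:
    """Rounded (2 dp, half-up) metrics report with the matrix included."""
    m = metrics(matrix)
    return {
        "matrix": matrix.counts.tolist(),
        "overall_accuracy": round2(m["overall_accuracy"]),
        "per_class": {
            name: {k: (round2(v) if v is not None else None) for k, v in vals.items()}
            for name, vals in m["per_class"].items()
        },
    }


def _labels_to_index(ds: SegmentDataset, ids) -> np.ndarray:
    by_id = ds.by_id()
    return np.array(
        [1 if by_id[i].label == ANOMALOUS else 0 for i in ids], dtype=np.int64
    )


def train(
    model: SegmentClassifier,
    split: DatasetSplit,
    ds: SegmentDataset,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[SegmentClassifier, TrainHistory]:
    """Train on the split's train ids, validating each epoch.

    If the split carries no validation ids, the train ids are further split
    ``(1 - val_fraction) / val_fraction`` stratified by class with the
    config seed.  Seeded end-to-end: weight init (model seed), shuffling and
    dropout (config seed).
    """
    train_ids = list(split.train_ids)
    val_ids = list(split.validation_ids)
    if not val_ids:
        train_ids, val_ids = _stratified_holdout(ds, train_ids, cfg.val_fraction, cfg.seed)
    if not train_ids or not val_ids:
        raise EvalError("train and validation sets must both be non-empty")

    x_train = model.prepare_input(ds.subset(train_ids).signal_matrix())
    y_train = _labels_to_index(ds, train_ids)
    x_val = model.prepare_input(ds.subset(val_ids).signal_matrix())
    y_val = _labels_to_index(ds, val_ids)
    if len(np.unique(y_train)) < 2:
        raise EvalError("training set must contain both classes")

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.net.params(), lr=cfg.learning_rate)
    history = TrainHistory()
    n = len(x_train)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            probs = model.net.forward(x_train[batch], training=True)
            losses.append(model.net.loss(probs, y_train[batch]) * len(batch))
            correct += int((label_from_proba(probs) == y_train[batch]).sum())
            model.net.backward(probs, y_train[batch])
            optimizer.step(model.net.grads())
        val_probs = model.net.forward(x_val, training=False)
        history.train_loss.append(sum(losses) / n)
        history.train_accuracy.append(100.0 * correct / n)
        history.val_loss.append(model.net.loss(val_probs, y_val))
        history.val_accuracy.append(
            100.0 * float((label_from_proba(val_probs) == y_val).mean())
        )
    return model, history


def _stratified_holdout(ds, ids, val_fraction, seed):
    by_id = ds.by_id()
    rng = np.random.default_rng(seed)
    train_out, val_out = [], []
    for label in CLASSES:
        members = sorted(i for i in ids if by_id[i].label == label)
        perm = rng.permutation(len(members))
        n_val = int(round(val_fraction * len(members)))
        val_out.extend(members[i] for i in perm[:n_val])
        train_out.extend(members[i] for i in perm[n_val:])
    return sorted(train_out), sorted(val_out)


def predict_segments(
    model: SegmentClassifier, ds: SegmentDataset, ids=None
) -> pd.DataFrame:
    """Per-segment probabilities and predicted label.

    Columns: record_id, segment_index, true_label, p_normal, p_anomalous,
    predicted_label.
    """
    ids = list(ids) if ids is not None else ds.ids
    sub = ds.subset(ids)
    probs = model.predict_proba(sub.signal_matrix())
    pred = label_from_proba(probs)
    return pd.DataFrame(
        {
            "record_id": [i[0] for i in ids],
            "segment_index": [i[1] for i in ids],
            "true_label": [CLASSES[j] for j in _labels_to_index(ds, ids)],
            "p_normal": probs[:, NORMAL_INDEX],
            "p_anomalous": probs[:, ANOMALOUS_INDEX],
            "predicted_label": [CLASSES[j] for j in pred],
        }
    )


def evaluate(model: SegmentClassifier, ds: SegmentDataset, ids=None) -> dict:
    """Segment-level report plus the patient-level roll-up."""
    preds = predict_segments(model, ds, ids)
    matrix = confusion(preds["true_label"], preds["predicted_label"])
    out = report(matrix)
    out["patient_level"] = aggregate_patient_level(preds)
    return out


def cross_validate(
    ds: SegmentDataset,
    pool_ids,
    model_config: ModelConfig = ModelConfig(),
    cfg: TrainConfig = TrainConfig(),
) -> pd.DataFrame:
    """k-fold cross-validation over a pool of segment ids.

    Each id is validated exactly once.  Returns one row per fold plus
    ``mean`` and ``sd`` (population standard deviation) rows, with columns
    accuracy, loss and anomalous recall.
    """
    by_id = ds.by_id()
    labels = {i: by_id[i].label for i in pool_ids}
    plan = make_folds(pool_ids, k=cfg.k, seed=cfg.seed, stratify_labels=labels)
    rows = []
    for fold, (train_ids, val_ids) in enumerate(plan.rounds()):
        model = build_model(model_config, seed=cfg.seed + fold)
        split = DatasetSplit(train_ids=train_ids, validation_ids=val_ids)
        model, history = train(model, split, ds, cfg)
        x_val = model.prepare_input(ds.subset(val_ids).signal_matrix())
        y_val = _labels_to_index(ds, val_ids)
        probs = model.net.forward(x_val, training=False)
        pred = label_from_proba(probs)
        matrix = confusion(y_val, pred)
        rec = metrics(matrix)["per_class"][ANOMALOUS]["recall"]
        rows.append(
            {
                "fold": fold,
                "accuracy": 100.0 * float((pred == y_val).mean()),
                "loss": cross_entropy(probs, y_val),
                "anomalous_recall": np.nan if rec is None else rec,
            }
        )
    df = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "fold": ["mean", "sd"],
            "accuracy": [df["accuracy"].mean(), df["accuracy"].std(ddof=0)],
            "loss": [df["loss"].mean(), df["loss"].std(ddof=0)],
            "anomalous_recall": [
                df["anomalous_recall"].mean(),
                df["anomalous_recall"].std(ddof=0),
            ],
        }
    )
    return pd.concat([df, summary], ignore_index=True)


def aggregate_patient_level(predictions: pd.DataFrame) -> dict:
    """Roll segment predictions up to per-recording alert flags.

    A recording's true status is anomalous iff it has at least one truly
    anomalous segment; it is *flagged* iff at least one segment is predicted
    anomalous.  Patient-level recall = flagged-and-true / true.  Recordings
    with zero segments cannot occur here (they contribute no rows).
    """
    required = {"record_id", "true_label", "predicted_label"}
    missing = required - set(predictions.columns)
    if missing:
        raise EvalError(f"predictions frame lacks columns: {sorted(missing)}")
    flags = []
    for rid, grp in predictions.groupby("record_id", sort=True):
        true_anom = bool((grp["true_label"] == ANOMALOUS).any())
        flagged = bool((grp["predicted_label"] == ANOMALOUS).any())
        flags.append({"record_id": rid, "true_anomalous": true_anom, "flagged": flagged})
    fdf = pd.DataFrame(flags)
    n_true = int(fdf["true_anomalous"].sum())
    n_detected = int((fdf["true_anomalous"] & fdf["flagged"]).sum())
    n_normal = len(fdf) - n_true
    n_false_alarm = int((~fdf["true_anomalous"] & fdf["flagged"]).sum())
    return {
        "records": flags,
        "n_records": len(fdf),
        "n_true_anomalous": n_true,
        "n_detected": n_detected,
        "recall": (100.0 * n_detected / n_true) if n_true else None,
        "n_true_normal": n_normal,
        "n_false_alarms": n_false_alarm,
    }
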