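"""Benign-vs-malignant classifiers and the evaluation metric suite.

Two architectures:

SCNN
    Six 3x3 convolutions (filter sizes 16, 32, 64, 128, 256, 256), three
    2x2 max-pools, two batch-norms, three 30% dropouts, then two rectified
    dense layers and a 2-way softmax.
DCNN
    A MobileNet-style depthwise-separable stack: a stride-2 stem
    convolution (ReLU, no normalisation) followed by 13 blocks of
    depthwise 3x3 + pointwise 1x1 convolutions, each conv followed by
    batch-norm and ReLU (26 norms, 27 ReLUs), explicit zero-padding before
    the four stride-2 depthwise convolutions, flatten and a 2-way softmax.

Both train with categorical cross-entropy, Adam by default, an exponential
learning-rate schedule with a floor, and early stopping on validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .nnet import (
    BatchNorm2D,
    Conv2D,
    Dense,
    DepthwiseConv2D,
    Dropout,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    ZeroPad2D,
    make_optimizer,
    refresh_batchnorm_stats,
    softmax,
    softmax_cce_with_logits,
)

__all__ = [
    "SCNNConfig",
    "DCNNConfig",
    "ConfusionMatrix",
    "EvalReport",
    "build_scnn",
    "build_dcnn",
    "lr_schedule",
    "train_classifier",
    "metrics_from_confusion",
    "roc_auc",
    "confusion_from_predictions",
    "evaluate",
]

CLASSES = ("benign", "malignant")  # index 0 = negative, 1 = positive


@dataclass(frozen=True)
class SCNNConfig:
    """Compact CNN settings; defaults follow the reference training setup."""

    conv_filters: tuple[int, ...] = (16, 32, 64, 128, 256, 256)
    dense_units: tuple[int, int] = (128, 64)
    dropout_rate: float = 0.30
    optimizer: str = "adam"
    initial_lr: float = 1e-5
    lr_floor: float = 1e-8
    decay: float = 0.8
    epochs: int = 50
    batch_size: int = 32
    early_stopping_min_delta: float = 0.01
    early_stopping_patience: int = 5
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dropout_rate < 1:
            raise ValueError("dropout rate must be in (0, 1)")
        if self.lr_floor >= self.initial_lr:
            raise ValueError("lr_floor must be below initial_lr")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    @property
    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(max(1, round(f * self.width_scale)) for f in self.conv_filters)


#: MobileNet-v1 block output channels; stride-2 depthwise at blocks 2, 4, 6, 12.
DCNN_BLOCK_CHANNELS = (64, 128, 128, 256, 256, 512, 512, 512, 512, 512, 512, 1024, 1024)
DCNN_STRIDE2_BLOCKS = (1, 3, 5, 11)  # 0-based indices


@dataclass(frozen=True)
class DCNNConfig:
    """Depthwise-separable CNN settings (MobileNet-style stem + 13 blocks)."""

    stem_filters: int = 32
    block_channels: tuple[int, ...] = DCNN_BLOCK_CHANNELS
    optimizer: str = "adam"
    initial_lr: float = 1e-4
    lr_floor: float = 1e-8
    decay: float = 0.8
    epochs: int = 50
    batch_size: int = 32
    early_stopping_min_delta: float = 0.001
    early_stopping_patience: int = 10
    width_scale: float = 1.0
    pretrained_weights: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.block_channels) != 13:
            raise ValueError("DCNN requires exactly 13 depthwise-separable blocks")
        if self.lr_floor >= self.initial_lr:
            raise ValueError("lr_floor must be below initial_lr")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")

    def _scale(self, c: int) -> int:
        return max(1, round(c * self.width_scale))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts (positive class = malignant)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass
class EvalReport:
    """Confusion matrix plus the derived metric suite.

    Metrics with a zero denominator are ``None`` (undefined, not 0) and
    listed in ``undefined``.  ``auc_eq15`` is the balanced-accuracy form
    0.5*(TPR + TNR); ``roc_auc`` is the threshold-free rank statistic.
    """

    confusion: ConfusionMatrix
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None
    specificity: float | None
    auc_eq15: float | None
    roc_auc: float | None = None
    undefined: tuple[str, ...] = ()
    specificity_literal_debug: float | None = None
    context: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------

def build_scnn(config: SCNNConfig, input_hw: tuple[int, int] = (224, 224), in_channels: int = 3) -> Sequential:
    """Sequential SCNN emitting 2-way logits (softmax applied at predict)."""
    rng = np.random.default_rng(config.seed)
    f = config.scaled_filters
    layers: list = []
    cin = in_channels
    h, w = input_hw
    # three conv pairs, pool after each pair; batch-norm after the first two
    # pools, dropout after every pool
    for pair in range(3):
        for j in range(2):
            cout = f[2 * pair + j]
            layers += [Conv2D(cin, cout, k=3, rng=rng), ReLU()]
            cin = cout
        layers.append(MaxPool2D(pool=2, stride=2))
        h, w = -(-h // 2), -(-w // 2)
        if pair < 2:
            layers.append(BatchNorm2D(cin))
        layers.append(Dropout(config.dropout_rate, rng=np.random.default_rng(config.seed + 1 + pair)))
    layers.append(Flatten())
    nin = h * w * cin
    for units in config.dense_units:
        layers += [Dense(nin, units, rng=rng), ReLU()]
        nin = units
    layers.append(Dense(nin, 2, rng=rng))
    return Sequential(layers)


def build_dcnn(config: DCNNConfig, input_hw: tuple[int, int] = (224, 224), in_channels: int = 3) -> Sequential:
    """Depthwise-separable classifier emitting 2-way logits."""
    rng = np.random.default_rng(config.seed)
    layers: list = []
    cin = config._scale(config.stem_filters)
    h, w = input_hw
    # stem: stride-2 conv + ReLU (no normalisation)
    layers += [Conv2D(in_channels, cin, k=3, stride=2, rng=rng), ReLU()]
    h, w = -(-h // 2), -(-w // 2)
    for i, cout in enumerate(config.block_channels):
        cout = config._scale(cout)
        stride = 2 if i in DCNN_STRIDE2_BLOCKS else 1
        if stride == 2:
            layers.append(ZeroPad2D(((0, 1), (0, 1))))
            layers.append(DepthwiseConv2D(cin, k=3, stride=2, padding="valid", rng=rng))
            h, w = h // 2, w // 2
        else:
            layers.append(DepthwiseConv2D(cin, k=3, stride=1, padding="same", rng=rng))
        layers += [BatchNorm2D(cin), ReLU()]
        layers += [Conv2D(cin, cout, k=1, rng=rng), BatchNorm2D(cout), ReLU()]
        cin = cout
    layers.append(Flatten())
    layers.append(Dense(h * w * cin, 2, rng=rng))
    return Sequential(layers)


def lr_schedule(epoch: int, initial_lr: float, decay: float, lr_floor: float) -> float:
    """Exponential decay with a floor: max(initial_lr * decay**epoch, lr_floor)."""
    if not 0 < decay < 1:
        raise ValueError(f"decay must be in (0, 1), got {decay}")
    return max(initial_lr * decay**epoch, lr_floor)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray) -> np.ndarray:
    y = np.zeros((len(labels), 2))
    y[np.arange(len(labels)), labels] = 1.0
    return y


def train_classifier(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: SCNNConfig | DCNNConfig,
) -> list[dict]:
    """Train with the scheduled learning rate and early stopping.

    ``y_*`` are integer labels (0 = benign, 1 = malignant).  Stops when
    validation loss fails to improve by ``min_delta`` for ``patience``
    consecutive epochs (patience 0 stops at the first non-improving epoch).
    Returns the per-epoch history (lr, loss, accuracy, val_loss, val_accuracy).
    """
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    x_train = _to_float(x_train)
    x_val = _to_float(x_val)
    rng = np.random.default_rng(config.seed)
    opt = make_optimizer(config.optimizer, config.initial_lr)
    yt = _onehot(y_train)
    history: list[dict] = []
    best_val = np.inf
    bad_epochs = 0
    for epoch in range(config.epochs):
        opt.lr = lr_schedule(epoch, config.initial_lr, config.decay, config.lr_floor)
        perm = rng.permutation(len(x_train))
        losses, correct = [], 0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            logits = model.forward(x_train[batch], training=True)
            loss, dlogits = softmax_cce_with_logits(logits, yt[batch])
            model.backward(dlogits)
            opt.step(model.params, model.grads)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y_train[batch]).sum())
        refresh_batchnorm_stats(model, x_train, batch_size=config.batch_size)
        val_logits = model.forward(x_val, training=False)
        val_loss, _ = softmax_cce_with_logits(val_logits, _onehot(y_val))
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "loss": float(np.mean(losses)),
                "accuracy": correct / len(x_train),
                "val_loss": val_loss,
                "val_accuracy": float((val_logits.argmax(axis=1) == y_val).mean()),
            }
        )
        if val_loss < best_val - config.early_stopping_min_delta:
            best_val = val_loss
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.early_stopping_patience:
                break
    return history


def _to_float(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.max() > 1.5:
        x = x / 255.0
    return x


def predict_proba(model: Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities (softmax over the 2-way logits)."""
    x = _to_float(x)
    out = []
    for start in range(0, len(x), batch_size):
        out.append(softmax(model.forward(x[start : start + batch_size], training=False)))
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _safe_div(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def metrics_from_confusion(cm: ConfusionMatrix, debug_literal_specificity: bool = False) -> EvalReport:
    """Precision, recall, F1, accuracy, specificity and balanced-accuracy AUC.

    Zero-denominator metrics come back as ``None`` and are flagged in
    ``undefined``.  ``debug_literal_specificity`` additionally reports the
    non-standard TP/(FP+FN) quantity for cross-checking printed tables.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and (precision + recall) > 0
        else None
    )
    accuracy = _safe_div(tp + tn, cm.total)
    specificity = _safe_div(tn, tn + fp)
    auc = 0.5 * (recall + specificity) if recall is not None and specificity is not None else None
    report = EvalReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        specificity=specificity,
        auc_eq15=auc,
        undefined=tuple(
            name
            for name, v in [
                ("precision", precision),
                ("recall", recall),
                ("f1", f1),
                ("accuracy", accuracy),
                ("specificity", specificity),
                ("auc_eq15", auc),
            ]
            if v is None
        ),
    )
    if debug_literal_specificity:
        report.specificity_literal_debug = _safe_div(tp, fp + fn)
    return report


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive scores above random negative).

    Ties count one half.  Raises if either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("roc_auc undefined: need both classes present")
    # rank-based computation, O(n log n)
    order = np.argsort(np.concatenate([pos, neg]), kind="mergesort")
    ranks = np.empty(len(order), dtype=float)
    combined = np.concatenate([pos, neg])[order]
    i = 0
    while i < len(combined):
        j = i
        while j + 1 < len(combined) and combined[j + 1] == combined[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(((y_pred == 1) & (y_true == 1)).sum()),
        tn=int(((y_pred == 0) & (y_true == 0)).sum()),
        fp=int(((y_pred == 1) & (y_true == 0)).sum()),
        fn=int(((y_pred == 0) & (y_true == 1)).sum()),
    )


def evaluate(
    model: Sequential,
    x_test: np.ndarray,
    y_test: np.ndarray,
    *,
    context: dict | None = None,
) -> EvalReport:
    """Full evaluation of a trained classifier on one test split."""
    if len(x_test) == 0:
        raise ValueError("empty test split")
    proba = predict_proba(model, x_test)
    y_pred = proba.argmax(axis=1)
    cm = confusion_from_predictions(y_test, y_pred)
    report = metrics_from_confusion(cm)
    y = np.asarray(y_test, dtype=int)
    if len(np.unique(y)) == 2:
        report.roc_auc = roc_auc(proba[:, 1], y)
    else:
        report.undefined = report.undefined + ("roc_auc",)
    report.context = dict(context or {})
    return report


def report_to_frame(reports: dict[tuple, EvalReport]) -> pd.DataFrame:
    """Tabulate per-(bin, magnification) reports for CSV export."""
    rows = []
    for key, r in reports.items():
        rows.append(
            {
                "bin": key[0],
                "magnification": key[1] if len(key) > 1 else "",
                "tp": r.confusion.tp,
                "tn": r.confusion.tn,
                "fp": r.confusion.fp,
                "fn": r.confusion.fn,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "accuracy": r.accuracy,
                "specificity": r.specificity,
                "auc_eq15": r.auc_eq15,
                "roc_auc": r.roc_auc,
            }
        )
    return pd.DataFrame(rows)
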