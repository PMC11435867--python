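"""Evaluation: confusion matrices, per-class recall/precision, AA/OA, maps.

Metric conventions are the standard ones: per-class recall is the diagonal
over the row (truth) sum, precision the diagonal over the column
(prediction) sum; average accuracy (AA) is the mean of the defined
per-class recalls and overall accuracy (OA) the trace over the total.
Percentages are reported to 4 decimal places. Classes that never occur
in the truth (empty confusion row) have undefined recall and are excluded
from AA with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .cube import HsiCube, LabelMap
from .model import MJHResNet
from .patches import mirror_pad

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "per_class_metrics",
    "aggregate",
    "average_accuracy",
    "evaluate_predictions",
    "classify_map",
    "render_label_png",
    "CLASS_PALETTE",
]

logger = logging.getLogger(__name__)

# fixed rendering palette per class index (1-based; 0 = unlabeled -> black)
CLASS_PALETTE = [
    (0, 0, 0),
    (230, 25, 75),
    (255, 255, 255),
    (255, 225, 25),
    (60, 60, 60),
    (245, 130, 48),
    (145, 30, 180),
    (70, 240, 240),
    (60, 180, 75),
    (0, 130, 200),
    (240, 50, 230),
    (170, 110, 40),
]


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """C x C count matrix, entry (i, j) = samples of true class i+1 predicted j+1."""
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.size == 0:
        raise ValueError("empty inputs")
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: truth {truth.shape}, pred {pred.shape}")
    c = int(n_classes or max(truth.max(), pred.max()))
    if truth.min() < 1 or pred.min() < 1 or max(truth.max(), pred.max()) > c:
        raise ValueError(f"labels must lie in 1..{c}")
    return _sk_confusion(truth, pred, labels=np.arange(1, c + 1)).astype(np.int64)


def per_class_metrics(confusion: np.ndarray) -> tuple:
    """Per-class (recall, precision) in percent; NaN where undefined.

    Recall_i = TP_i / (TP_i + FN_i) (row-normalized diagonal);
    Precision_i = TP_i / (TP_i + FP_i) (column-normalized diagonal).
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(cm)
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, tp / row, np.nan) * 100.0
        precision = np.where(col > 0, tp / col, np.nan) * 100.0
    n_empty = int(np.sum(row == 0))
    if n_empty:
        logger.warning("per_class_metrics: %d class(es) absent from truth; recall undefined", n_empty)
    return recall, precision


def average_accuracy(recalls) -> float:
    """AA in percent: the mean of the defined per-class recalls (already in %)."""
    recalls = np.asarray(recalls, dtype=float)
    defined = recalls[~np.isnan(recalls)]
    if defined.size == 0:
        raise ValueError("no defined per-class recalls")
    return float(defined.mean())


def aggregate(confusion: np.ndarray) -> tuple:
    """(AA, OA) in percent from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    recall, _ = per_class_metrics(cm)
    aa = average_accuracy(recall)
    oa = 100.0 * np.trace(cm) / total
    return aa, float(oa)


@dataclass
class EvalReport:
    """Confusion matrix plus derived per-class and aggregate metrics (%)."""

    confusion: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    aa: float
    oa: float
    class_names: list = field(default_factory=list)

    def to_text(self) -> str:
        names = self.class_names or [f"class_{i + 1}" for i in range(self.confusion.shape[0])]
        lines = ["class\trecall\tprecision"]
        for name, r, p in zip(names, self.recall, self.precision):
            lines.append(f"{name}\t{r:.4f}\t{p:.4f}")
        lines.append(f"AA\t{self.aa:.4f}")
        lines.append(f"OA\t{self.oa:.4f}")
        return "\n".join(lines)


def evaluate_predictions(truth, pred, class_names: list | None = None) -> EvalReport:
    n_classes = len(class_names) if class_names else None
    cm = confusion_matrix(truth, pred, n_classes=n_classes)
    recall, precision = per_class_metrics(cm)
    aa, oa = aggregate(cm)
    return EvalReport(cm, recall, precision, aa, oa, class_names or [])


def classify_map(model: MJHResNet, cube: HsiCube, patch_size: int,
                 class_values: np.ndarray | None = None,
                 batch_size: int = 1024) -> LabelMap:
    """Classify every pixel from its mirror-padded patch; returns a LabelMap.

    ``class_values`` maps the model's 0-based outputs to label values
    (defaults to 1..n_classes). Deterministic for a fixed model.
    """
    if cube.bands != model.config.in_bands:
        raise ValueError(f"cube has {cube.bands} bands but the model expects {model.config.in_bands}")
    s = patch_size
    if s % 2 == 0:
        raise ValueError("patch size must be odd")
    half = s // 2
    padded = mirror_pad(np.asarray(cube.data, dtype=np.float32), half)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (s, s), axis=(0, 1))
    if class_values is None:
        class_values = np.arange(1, model.config.n_classes + 1)
    out = np.empty(cube.rows * cube.cols, dtype=np.int32)
    flat = windows.reshape(cube.rows * cube.cols, cube.bands, s, s)
    for i in range(0, flat.shape[0], batch_size):
        xb = np.ascontiguousarray(flat[i : i + batch_size])
        logits = model.forward(xb, train=False)
        out[i : i + batch_size] = class_values[logits.argmax(axis=1)]
    return LabelMap(out.reshape(cube.rows, cube.cols), [])


def render_label_png(labels: LabelMap, path: str) -> None:
    """Write a label map as an indexed-palette PNG with the fixed class palette."""
    from PIL import Image

    arr = labels.labels.astype(np.uint8)
    img = Image.fromarray(arr, mode="P")
    palette = []
    for i in range(256):
        palette.extend(CLASS_PALETTE[i % len(CLASS_PALETTE)] if i < len(CLASS_PALETTE) else (0, 0, 0))
    img.putpalette(palette)
    img.save(path)
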