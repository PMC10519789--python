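"""Classification metrics from confusion matrices, and Grad-CAM heatmaps.

Metric definitions are the usual one-vs-rest contingency quantities: for
class k, TP is the diagonal entry, FP the rest of its predicted column, FN
the rest of its true row and TN everything else.  Precision, recall and F1
follow, macro averages are unweighted means over classes, and accuracy is
the trace over the total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .autograd import Tensor


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.size == 0:
            raise ValueError("confusion matrix must be square and non-empty")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion matrix entries must be nonnegative ints")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_predictions(cls, y_true, y_pred, num_classes: int | None = None
                         ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        k = num_classes or int(max(y_true.max(), y_pred.max())) + 1
        counts = np.zeros((k, k), dtype=np.int64)
        np.add.at(counts, (y_true, y_pred), 1)
        return cls(counts)

    @property
    def num_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(TP, FP, FN, TN) arrays, one entry per class."""
        tp = np.diag(self.counts)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def to_dict(self, classes: tuple[str, ...] | None = None) -> dict:
        k = len(self.precision)
        names = classes or tuple(str(i) for i in range(k))
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {names[i]: {"precision": float(self.precision[i]),
                                     "recall": float(self.recall[i]),
                                     "f1": float(self.f1[i])}
                          for i in range(k)},
        }


def _safe_divide(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    bad = den == 0
    if bad.any():
        warnings.warn(f"{what} undefined for classes {np.where(bad)[0].tolist()} "
                      "(zero denominator); reporting 0", stacklevel=3)
    np.divide(num, den, out=out, where=~bad)
    return out


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1 and their macro averages.

    Macro-F1 is the unweighted mean of per-class F1 scores (not the harmonic
    mean of the macro precision and recall).  Zero-denominator classes score
    0 with a warning.
    """
    if (cm.counts.sum(axis=1) == 0).any():
        raise ValueError("every class needs at least one true sample")
    tp, fp, fn, _ = cm.per_class_counts()
    precision = _safe_divide(tp, tp + fp, "precision")
    recall = _safe_divide(tp, tp + fn, "recall")
    f1 = _safe_divide(2 * precision * recall, precision + recall, "F1")
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


def accuracy_from_per_class(tp_list, fp_list, total: int) -> float:
    """Overall accuracy from per-class TP/FP counts.

    Each false positive is exactly one misclassified image, so accuracy is
    (total - sum(FP)) / total; consistency requires sum(TP) + sum(FP) == total.
    """
    tp = np.asarray(tp_list, dtype=np.int64)
    fp = np.asarray(fp_list, dtype=np.int64)
    if total <= 0 or (tp < 0).any() or (fp < 0).any():
        raise ValueError("counts must be nonnegative and total positive")
    if tp.sum() + fp.sum() != total:
        raise ValueError(f"inconsistent counts: TP+FP sums to "
                         f"{int(tp.sum() + fp.sum())}, expected {total}")
    return float((total - fp.sum()) / total)


# -- Grad-CAM ------------------------------------------------------------------

@dataclass(frozen=True)
class CamHeatmap:
    """H x W class-activation map, min-max normalised to [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 2 or not np.isfinite(v).all():
            raise ValueError("heatmap must be a finite 2-D array")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap must be normalised to [0, 1]")
        object.__setattr__(self, "values", v)


def grad_cam(model, image: np.ndarray, target_class: int,
             layer: str | None = None) -> CamHeatmap:
    """Gradient-weighted class activation map for one image.

    The chosen layer's channels are combined with weights equal to the
    spatial mean of the class-score gradient, rectified, bilinearly
    upsampled to the input size and min-max normalised (an all-zero map is
    returned unchanged when gradients vanish).

    Parameters
    ----------
    model:
        A built classifier (see :func:`fcaeffnet.architecture.build_model`).
    image:
        (3, H, W) standardised input.
    layer:
        One of ``model.layer_names()``; defaults to the deepest bottleneck
        block's output.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a single (3, H, W) image")
    names = model.layer_names()
    layer = layer or names[-2]              # last bottleneck block
    if layer not in names:
        raise ValueError(f"unknown layer {layer!r}; expected one of {names}")
    if not 0 <= target_class < model.spec.num_classes:
        raise ValueError(f"target_class {target_class} out of range")
    was_training = model.training
    model.eval()
    try:
        x = Tensor(image[None], requires_grad=True)
        logits = model.forward(x, capture=layer)
        act = model._captured
        onehot = np.zeros_like(logits.data)
        onehot[0, target_class] = 1.0
        logits.backward(onehot)
        a = act.data[0]                     # (C, h, w)
        g = act.grad[0] if act.grad is not None else np.zeros_like(a)
        weights = g.mean(axis=(1, 2))
        cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    finally:
        model.train(was_training)
    h, w = image.shape[1:]
    if cam.shape != (h, w):
        cam = zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
        cam = np.maximum(cam, 0.0)
    spread = cam.max() - cam.min()
    if spread > 0:
        cam = (cam - cam.min()) / spread
    elif cam.max() > 0:          # constant positive map (e.g. 1x1 source)
        cam = np.ones_like(cam)
    return CamHeatmap(cam.astype(np.float32))
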