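"""Classification and image-quality metrics.

Classification metrics follow the usual one-vs-rest reading of a confusion
matrix: per-class precision P = TP/(TP+FP) * 100, recall R = TP/(TP+FN) * 100,
F1 = 2PR/(P+R), overall accuracy = trace/total * 100.  Average precision is
the area under the precision-recall step curve (right-continuous, no
smoothing); mAP averages AP over classes.

Image quality compares two equally sized images on the [0, 1] intensity
scale: RMSE, PSNR = 20 log10(1/RMSE), SSIM (11x11 Gaussian window,
sigma 1.5, K1 = 0.01, K2 = 0.03) and the relative greyscale Shannon-entropy
difference in percent (256-bin histograms).  The entropy statistic is
defined by this package.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "QualityReport",
    "classification_metrics",
    "average_precision",
    "mean_average_precision",
    "image_quality_report",
    "shannon_entropy",
    "michelson_contrast",
]


@dataclass
class ConfusionMatrix:
    """Square count table; rows are true classes, columns predictions."""

    class_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.class_labels)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square and match class labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.rint(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.counts, index=list(self.class_labels), columns=list(self.class_labels)
        ).to_csv(path)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (percent) plus overall accuracy."""

    class_labels: tuple[str, ...]
    precision: np.ndarray  # percent
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    undefined: dict  # label -> list of metric names reported as 0 by convention
    confusion: ConfusionMatrix
    map_percent: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.class_labels),
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )

    def to_json(self, path=None) -> str:
        doc = {
            "classes": list(self.class_labels),
            "precision_percent": self.precision.tolist(),
            "recall_percent": self.recall.tolist(),
            "f1_percent": self.f1.tolist(),
            "accuracy_percent": self.accuracy,
            "map_percent": self.map_percent,
            "undefined": self.undefined,
            "confusion": self.confusion.counts.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest precision/recall/F1 and overall accuracy from a confusion
    matrix.  Classes with zero TP+FP (or TP+FN) get 0 for the affected metric
    and are listed in the report's ``undefined`` map instead of raising."""
    counts = cm.counts.astype(float)
    n = counts.shape[0]
    if n < 1:
        raise ValueError("confusion matrix needs at least one class")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    undefined: dict[str, list[str]] = {}
    precision = np.zeros(n)
    recall = np.zeros(n)
    f1 = np.zeros(n)
    for i, label in enumerate(cm.class_labels):
        flags = []
        if tp[i] + fp[i] > 0:
            precision[i] = 100.0 * tp[i] / (tp[i] + fp[i])
        else:
            flags.append("precision")
        if tp[i] + fn[i] > 0:
            recall[i] = 100.0 * tp[i] / (tp[i] + fn[i])
        else:
            flags.append("recall")
        if precision[i] + recall[i] > 0:
            f1[i] = 2.0 * precision[i] * recall[i] / (precision[i] + recall[i])
        elif flags:
            flags.append("f1")
        if flags:
            undefined[label] = flags
    total = counts.sum()
    accuracy = 100.0 * tp.sum() / total if total > 0 else 0.0
    return MetricsReport(
        cm.class_labels, precision, recall, f1, float(accuracy), undefined, cm
    )


def average_precision(scores, labels) -> float:
    """Area under the precision-recall step curve (right-continuous).

    Items are ranked by descending score (stable order for ties); AP is the
    mean of precision-at-k over the positions k of the positive items.
    Invariant to strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_tp = np.cumsum(ranked)
    k = np.arange(1, scores.size + 1)
    precision_at_k = cum_tp / k
    return float(precision_at_k[ranked].sum() / n_pos)


def mean_average_precision(per_class) -> float:
    """Mean over classes of average precision; ``per_class`` is an iterable
    of (scores, labels) pairs."""
    aps = [average_precision(s, y) for s, y in per_class]
    if not aps:
        raise ValueError("mAP needs at least one class")
    return float(np.mean(aps))


@dataclass
class QualityReport:
    rmse: float
    psnr_db: float  # math.inf for identical images
    ssim: float
    entropy_diff_percent: float

    def to_json(self, path=None) -> str:
        doc = {
            "rmse": self.rmse,
            "psnr_db": None if math.isinf(self.psnr_db) else self.psnr_db,
            "ssim": self.ssim,
            "entropy_diff_percent": self.entropy_diff_percent,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _to_unit(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float) / 255.0
    return img.astype(float)


def _grey(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        # ITU-R BT.601 luma weights
        return img @ np.array([0.299, 0.587, 0.114])
    return img


def shannon_entropy(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the greyscale intensity histogram."""
    grey = _grey(_to_unit(img))
    hist, _ = np.histogram(grey, bins=bins, range=(0.0, 1.0))
    p = hist[hist > 0] / grey.size
    return float(-np.sum(p * np.log2(p)))


def michelson_contrast(foreground_intensity: float, background_intensity: float) -> float:
    """(Imax - Imin) / (Imax + Imin) for a pair of mean intensities."""
    hi = max(foreground_intensity, background_intensity)
    lo = min(foreground_intensity, background_intensity)
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def _ssim(a: np.ndarray, b: np.ndarray) -> float:
    """SSIM with the standard 11x11 Gaussian window (sigma 1.5).

    Images smaller than the window fall back to a single global window
    (full-image means/variances in the SSIM formula), so tiny fixtures and
    degenerate inputs remain comparable."""
    side = min(a.shape[0], a.shape[1])
    if side >= 11:
        return float(
            structural_similarity(
                a,
                b,
                data_range=1.0,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
                K1=0.01,
                K2=0.03,
                channel_axis=-1 if a.ndim == 3 else None,
            )
        )
    c1, c2 = 0.01**2, 0.03**2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(
        (2 * mu_a * mu_b + c1)
        * (2 * cov + c2)
        / ((mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2))
    )


def image_quality_report(image_a, image_b) -> QualityReport:
    """Compare two images (uint8 or float on [0, 1]) of identical shape."""
    a = _to_unit(image_a)
    b = _to_unit(image_b)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    psnr = math.inf if rmse == 0 else 20.0 * math.log10(1.0 / rmse)
    ssim = _ssim(a, b)
    ha = shannon_entropy(a)
    hb = shannon_entropy(b)
    if hb == 0:
        ediff = 0.0 if ha == 0 else math.inf
    else:
        ediff = abs(ha - hb) / hb * 100.0
    return QualityReport(rmse, psnr, ssim, ediff)
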