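"""Pixel-level binary segmentation metrics.

Four metrics are reported, all as percentages of the pixel-level
confusion counts (foreground = 1):

* accuracy     = (TP + TN) / total
* precision    = TP / (TP + FP)
* specificity  = TN / (TN + FP)
* mIoU         = ½ · [TP/(TP+FP+FN) + TN/(TN+FN+FP)]

mIoU is the two-class mean of foreground and background
intersection-over-union.  A metric whose denominator is zero is reported
as *undefined* (``None``), never silently zeroed.  Dataset evaluation is
micro-averaged by default: confusion counts are pooled over all pixels of
all images before the ratios are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metric_report",
           "evaluate_dataset"]

METRIC_NAMES = ("accuracy", "precision", "specificity", "miou")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """The four metrics as percentages; ``None`` marks an undefined ratio."""

    accuracy: float | None
    precision: float | None
    specificity: float | None
    miou: float | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(n for n in METRIC_NAMES if getattr(self, n) is None)

    def as_row(self, fmt: str = "{:.2f}", na: str = "NA") -> list[str]:
        return [fmt.format(v) if v is not None else na
                for v in (self.accuracy, self.precision, self.specificity, self.miou)]


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies; both masks must be strictly binary."""
    p = np.asarray(pred_mask)
    t = np.asarray(truth_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    for name, a in (("pred", p), ("truth", t)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary; threshold it first")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))


def _ratio(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metric_report(counts: ConfusionCounts) -> MetricReport:
    if counts.total <= 0:
        raise ValueError("empty confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    iou_fg = _ratio(tp, tp + fp + fn)
    iou_bg = _ratio(tn, tn + fn + fp)
    miou = None if iou_fg is None or iou_bg is None else (iou_fg + iou_bg) / 2.0
    return MetricReport(
        accuracy=_ratio(tp + tn, counts.total),
        precision=_ratio(tp, tp + fp),
        specificity=_ratio(tn, tn + fp),
        miou=miou)


def evaluate_dataset(model, pairs, threshold: float = 0.5,
                     average: str = "micro") -> MetricReport:
    """Evaluate a realized model on image/mask pairs.

    ``micro`` pools confusion counts over all pixels of all images (the
    default); ``macro`` averages per-image reports, skipping undefined
    entries per metric.
    """
    from .model import predict

    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty dataset")
    if average not in ("micro", "macro"):
        raise ValueError(f"average must be 'micro' or 'macro', got {average!r}")

    per_image = []
    for s in pairs:
        prob = predict(model, s.image)
        pred = (prob >= threshold).astype(np.uint8)
        per_image.append(confusion(pred, np.asarray(s.mask).astype(np.uint8)))

    if average == "micro":
        pooled = per_image[0]
        for c in per_image[1:]:
            pooled = pooled + c
        return metric_report(pooled)

    reports = [metric_report(c) for c in per_image]
    means = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return MetricReport(**means)
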