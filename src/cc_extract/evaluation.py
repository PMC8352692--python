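"""Mask-versus-ground-truth scoring: overlap, confusion-matrix rates and
area measures.

Given an extracted mask and an expert (or phantom) ground truth, the pixel
confusion counts TP/FP/TN/FN yield the overlap scores

* Jaccard ``TP / (TP + FP + FN)`` and Dice ``2 TP / (2 TP + FP + FN)``
  (related by ``D = 2J / (1 + J)``),

and the statistical rates sensitivity ``TP/(TP+FN)``, specificity
``TN/(TN+FP)``, accuracy and precision.  The false-negative and
false-positive rates are the exact complements ``1 - sensitivity`` and
``1 - specificity`` (computed as such, so the complement identities hold to
the last bit); union-normalized set-difference variants are available via
``legacy_setrates=True``.  Area measures report the total brain area (TBA)
and corpus-callosum area (CCA) in pixels together with image-normalized
fractions and the CCA/TBA ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AreaReport",
    "confusion",
    "similarity_metrics",
    "statistical_metrics",
    "metrics_report",
    "area_measures",
    "batch_evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts; tp+fp+tn+fn equals the image size."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The eight scores plus the counts they derive from.

    ``flags`` names any rate whose denominator was zero (reported as 0).
    """

    jaccard: float
    dice: float
    fpr: float
    fnr: float
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    counts: ConfusionCounts
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class AreaReport:
    """Total brain area and corpus-callosum area, raw and normalized."""

    tba_pixels: int
    cca_pixels: int
    cca_over_tba: float
    tba_norm: float
    cca_norm: float


def _as_mask(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("masks must be binary (values 0/1 or bool)")
        m = m.astype(bool)
    return m


def confusion(gt: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted mask against ground truth."""
    gt = _as_mask(gt)
    pred = _as_mask(pred)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: gt {gt.shape} vs pred {pred.shape}")
    tp = int(np.count_nonzero(gt & pred))
    fp = int(np.count_nonzero(~gt & pred))
    fn = int(np.count_nonzero(gt & ~pred))
    tn = int(np.count_nonzero(~gt & ~pred))
    return ConfusionCounts(tp, fp, tn, fn)


def similarity_metrics(counts: ConfusionCounts, legacy_setrates: bool = False):
    """(jaccard, dice, fpr, fnr) from confusion counts.

    Default rates are confusion-matrix complements (``fnr = 1 - sensitivity``,
    ``fpr = 1 - specificity``); ``legacy_setrates=True`` instead normalizes
    the set differences by the union: ``fpr = FP/|union|, fnr = FN/|union|``.
    Both masks empty gives jaccard = dice = 1 (perfect agreement on nothing).
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    union = tp + fp + fn
    if union == 0:
        jaccard = dice = 1.0
    else:
        jaccard = tp / union
        dice = 2 * tp / (2 * tp + fp + fn)
    if legacy_setrates:
        fpr = fp / union if union else 0.0
        fnr = fn / union if union else 0.0
    else:
        fpr = 1.0 - (tn / (tn + fp)) if tn + fp else 0.0
        fnr = 1.0 - (tp / (tp + fn)) if tp + fn else 0.0
    return jaccard, dice, fpr, fnr


def statistical_metrics(counts: ConfusionCounts):
    """(sensitivity, specificity, accuracy, precision); zero denominators
    yield 0 (callers can inspect the counts)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    accuracy = (tp + tn) / counts.total if counts.total else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    return sensitivity, specificity, accuracy, precision


def metrics_report(gt: np.ndarray, pred: np.ndarray,
                   legacy_setrates: bool = False) -> MetricsReport:
    """Full scoring of a predicted mask against ground truth."""
    counts = confusion(gt, pred)
    jaccard, dice, fpr, fnr = similarity_metrics(counts, legacy_setrates)
    sens, spec, acc, prec = statistical_metrics(counts)
    flags = []
    if counts.tp + counts.fn == 0:
        flags.append("sensitivity")
    if counts.tn + counts.fp == 0:
        flags.append("specificity")
    if counts.tp + counts.fp == 0:
        flags.append("precision")
    return MetricsReport(jaccard, dice, fpr, fnr, sens, spec, acc, prec,
                         counts, tuple(flags))


def area_measures(brain_mask: np.ndarray, cc_mask: np.ndarray) -> AreaReport:
    """TBA / CCA pixel counts, their ratio, and image-normalized fractions."""
    brain = _as_mask(brain_mask)
    cc = _as_mask(cc_mask)
    if brain.shape != cc.shape:
        raise ValueError("brain and cc masks must share a shape")
    tba = int(np.count_nonzero(brain))
    cca = int(np.count_nonzero(cc))
    return AreaReport(
        tba_pixels=tba,
        cca_pixels=cca,
        cca_over_tba=cca / tba if tba else 0.0,
        tba_norm=tba / brain.size,
        cca_norm=cca / cc.size,
    )


_METRIC_COLUMNS = [
    "jaccard", "dice", "fpr", "fnr",
    "sensitivity", "specificity", "accuracy", "precision",
]


def batch_evaluate(pairs) -> pd.DataFrame:
    """Score a batch of ``(gt, pred)`` or ``(gt, pred, brain_mask)`` items.

    Returns one row per item plus an unweighted arithmetic ``mean`` row;
    when a brain mask is supplied the TBA/CCA measures are included.
    """
    rows = []
    for item in pairs:
        gt, pred = item[0], item[1]
        brain = item[2] if len(item) > 2 else None
        rep = metrics_report(gt, pred)
        row = {c: getattr(rep, c) for c in _METRIC_COLUMNS}
        if brain is not None:
            area = area_measures(brain, pred)
            row.update(
                tba_pixels=area.tba_pixels,
                cca_pixels=area.cca_pixels,
                cca_over_tba=area.cca_over_tba,
            )
        rows.append(row)
    df = pd.DataFrame(rows, index=[f"image_{i + 1}" for i in range(len(rows))])
    if len(df):
        df.loc["mean"] = df.mean(axis=0)
    return df
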