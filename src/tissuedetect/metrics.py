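"""Segmentation metrics for tissue masks: IoU, Dice, and aggregation.

Predicted and ground-truth masks are binarized (any value > 0 counts as
tissue), the prediction is resized to the ground-truth resolution with
nearest-neighbor interpolation if the shapes differ, and pixel-level
confusion counts are accumulated with tissue as the positive class:

    IoU  = TP / (TP + FP + FN)
    Dice = 2·TP / (2·TP + FP + FN) = 2·IoU / (1 + IoU)

When both masks are empty the score is 1.0 by convention — a correctly
empty prediction is not penalized. Aggregate scores are unweighted
arithmetic means over slides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "ConfusionCounts",
    "SlideMetrics",
    "confusion_counts",
    "iou_score",
    "dice_score",
    "evaluate_pair",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts with tissue as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with background as the positive class."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class SlideMetrics:
    """Per-slide evaluation record for one detector."""

    slide_id: str
    method: str
    iou: float
    dice: float
    runtime_s: float = 0.0
    cohort: str | None = None


def _binarize(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    return mask > 0


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of a prediction against ground truth.

    If shapes differ the prediction is resized to the truth's shape
    with nearest-neighbor interpolation (preserving binarity) before
    counting.
    """
    p = _binarize(pred)
    t = _binarize(truth)
    if p.shape != t.shape:
        p = _sk_resize(
            p.astype(np.uint8), t.shape, order=0, anti_aliasing=False,
            preserve_range=True,
        ) > 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def iou_score(c: ConfusionCounts) -> float:
    """Intersection over union (Jaccard); 1.0 when both masks are empty."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def dice_score(c: ConfusionCounts) -> float:
    """Dice coefficient; 1.0 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def evaluate_pair(
    pred: np.ndarray,
    truth: np.ndarray,
    slide_id: str = "",
    method: str = "",
    runtime_s: float = 0.0,
    cohort: str | None = None,
    per_class_mean: bool = False,
) -> SlideMetrics:
    """Evaluate one predicted mask against its ground truth.

    With ``per_class_mean`` the reported IoU/Dice are averaged over the
    tissue and background classes instead of the tissue-foreground
    scores.
    """
    c = confusion_counts(pred, truth)
    if per_class_mean:
        cb = c.swapped()
        iou = 0.5 * (iou_score(c) + iou_score(cb))
        dice = 0.5 * (dice_score(c) + dice_score(cb))
    else:
        iou = iou_score(c)
        dice = dice_score(c)
    return SlideMetrics(
        slide_id=slide_id, method=method, iou=iou, dice=dice,
        runtime_s=runtime_s, cohort=cohort,
    )


def aggregate(
    results: Sequence[SlideMetrics],
    group_key: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Unweighted arithmetic means per method (and optionally per cohort).

    Parameters
    ----------
    results
        Per-slide records.
    group_key
        Optional mapping slide_id → cohort; overrides any cohort
        already stored on the records. When any cohort is present the
        report has one row per (method, cohort).

    Returns
    -------
    DataFrame with columns ``method`` (, ``cohort``), ``n``,
    ``mean_iou``, ``mean_dice``, ``mean_runtime_s``.
    """
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    rows = []
    for r in results:
        cohort = r.cohort
        if group_key is not None:
            cohort = group_key.get(r.slide_id, cohort)
        rows.append(
            {
                "slide_id": r.slide_id,
                "method": r.method,
                "cohort": cohort,
                "iou": r.iou,
                "dice": r.dice,
                "runtime_s": r.runtime_s,
            }
        )
    df = pd.DataFrame(rows)
    keys = ["method"]
    if df["cohort"].notna().any():
        keys.append("cohort")
    agg = (
        df.groupby(keys, dropna=False)
        .agg(
            n=("iou", "size"),
            mean_iou=("iou", "mean"),
            mean_dice=("dice", "mean"),
            mean_runtime_s=("runtime_s", "mean"),
        )
        .reset_index()
    )
    return agg
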