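"""Pixel-wise accuracy against ground truth and per-method summaries.

The headline measure is overall pixel agreement (the share of pixels on
which prediction and truth agree), which is what threshold-detection
comparisons in this area report. Because overall accuracy is sensitive
to class imbalance, each record also carries IoU, precision and recall
of the vegetation class as supplementary columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .colorspace import validate_mask

__all__ = ["AccuracyRecord", "pixel_accuracy", "evaluate_pair", "summarize",
           "records_to_csv"]


@dataclass(frozen=True)
class AccuracyRecord:
    image_id: str
    method: str
    accuracy_pct: float
    n_pixels: int
    iou: float = np.nan
    precision: float = np.nan
    recall: float = np.nan


def pixel_accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of pixels where the two masks agree."""
    pred = validate_mask(pred)
    truth = validate_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(
            f"mask dimensions differ: {pred.shape} vs {truth.shape}"
        )
    return 100.0 * float(np.mean(pred == truth))


def evaluate_pair(
    pred: np.ndarray, truth: np.ndarray, *, image_id: str = "", method: str = ""
) -> AccuracyRecord:
    """Full record for one predicted/truth mask pair."""
    acc = pixel_accuracy(pred, truth)
    p = np.asarray(pred) == 255
    t = np.asarray(truth) == 255
    inter = float(np.sum(p & t))
    union = float(np.sum(p | t))
    pred_pos = float(np.sum(p))
    true_pos = float(np.sum(t))
    return AccuracyRecord(
        image_id=image_id,
        method=method,
        accuracy_pct=acc,
        n_pixels=int(p.size),
        iou=inter / union if union else np.nan,
        precision=inter / pred_pos if pred_pos else np.nan,
        recall=inter / true_pos if true_pos else np.nan,
    )


def summarize(
    records: Iterable[AccuracyRecord], *, population_std: bool = False
) -> pd.DataFrame:
    """Per-method mean and standard deviation of accuracy.

    Sample standard deviation (ddof=1) by default; a single record per
    method then yields NaN std. Set ``population_std`` for ddof=0.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no accuracy records to summarize")
    df = pd.DataFrame([r.__dict__ for r in recs])
    ddof = 0 if population_std else 1
    out = df.groupby("method")["accuracy_pct"].agg(
        mean="mean", std=lambda s: s.std(ddof=ddof), n="count"
    )
    return out.reset_index()


def records_to_csv(records: Iterable[AccuracyRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)
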