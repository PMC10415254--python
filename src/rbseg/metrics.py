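"""Pixel-level segmentation metrics: Sørensen–Dice, sensitivity, specificity,
accuracy, and the least/highest/average summaries used for reporting.

Conventions for degenerate inputs: Dice of two empty masks is 1.0 (perfect
agreement on absence), and a sensitivity/specificity with an empty reference
class is 1.0; both cases emit a log warning so that reports built from
pathological inputs are traceable.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class SegMetrics:
    sdc: float
    sensitivity: float
    specificity: float
    accuracy: float


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion tallies; positive class = lesion (1)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for m, name in ((pred, "pred"), (truth, "truth")):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        TP=int(np.count_nonzero(p & t)),
        FP=int(np.count_nonzero(p & ~t)),
        FN=int(np.count_nonzero(~p & t)),
        TN=int(np.count_nonzero(~p & ~t)),
    )


def dice(c: ConfusionCounts) -> float:
    """Sørensen–Dice coefficient ``2 TP / (2 TP + FP + FN)``."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        logger.warning("Dice of two empty masks: returning 1.0")
        return 1.0
    return 2 * c.TP / denom


def classification_metrics(c: ConfusionCounts) -> SegMetrics:
    """Dice plus sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy."""

    def ratio(num: int, denom: int, name: str) -> float:
        if denom == 0:
            logger.warning("%s has an empty denominator: returning 1.0", name)
            return 1.0
        return num / denom

    return SegMetrics(
        sdc=dice(c),
        sensitivity=ratio(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=ratio(c.TN, c.TN + c.FP, "specificity"),
        accuracy=ratio(c.TP + c.TN, c.total, "accuracy"),
    )


def summarize_scores(scores: list[float]) -> dict[str, float]:
    """Least / highest / average of a non-empty score list."""
    if len(scores) == 0:
        raise ValueError("cannot summarize an empty score list")
    arr = np.asarray(scores, dtype=float)
    return {
        "least": float(arr.min()),
        "highest": float(arr.max()),
        "average": float(arr.mean()),
    }


def evaluate_pairs(
    preds: list[np.ndarray], truths: list[np.ndarray], ids: list[str] | None = None
) -> list[dict]:
    """Per-image confusion counts and metrics for aligned mask pairs."""
    if len(preds) != len(truths):
        raise ValueError("prediction and truth lists differ in length")
    ids = ids or [f"image_{i:05d}" for i in range(len(preds))]
    rows = []
    for image_id, p, t in zip(ids, preds, truths):
        c = confusion_counts(p, t)
        m = classification_metrics(c)
        rows.append({"image_id": image_id, **asdict(c), **asdict(m)})
    return rows


def write_report(rows: list[dict], csv_path: str | Path, json_path: str | Path) -> dict:
    """Write the per-image CSV and the least/highest/average JSON summary."""
    if not rows:
        raise ValueError("no evaluation rows to report")
    csv_path, json_path = Path(csv_path), Path(json_path)
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    summary = {
        metric: summarize_scores([r[metric] for r in rows])
        for metric in ("sdc", "sensitivity", "specificity", "accuracy")
    }
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
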