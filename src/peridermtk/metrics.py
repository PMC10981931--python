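"""Pixel-level segmentation benchmarking against expert annotation.

Per tissue class, predictions are scored one-vs-rest with

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

where TP/FP/FN are pixel counts. Scores are reported per slide before and
after postprocessing, plus unweighted averages across slides. Periderm is
the class of interest; endoderm and lateral-root scores are computed too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import CLASS_MAP, LabelMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest pixel counts for a single class."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion_counts(pred: LabelMask, truth: LabelMask, class_code: int) -> ConfusionCounts:
    """Count TP/FP/FN pixels of one class between prediction and truth."""
    if pred.labels.shape != truth.labels.shape:
        raise ValueError(
            f"mask dimensions differ: pred {pred.labels.shape} vs truth {truth.labels.shape}"
        )
    p = pred.labels == class_code
    t = truth.labels == class_code
    tp = int(np.count_nonzero(p & t))
    return ConfusionCounts(tp=tp, fp=int(p.sum()) - tp, fn=int(t.sum()) - tp)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); 0 when nothing was predicted positive (logged)."""
    denom = c.tp + c.fp
    if denom == 0:
        logger.info("precision undefined (no predicted positives); returning 0")
        return 0.0
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN); 0 when the class is absent from the truth (logged)."""
    denom = c.tp + c.fn
    if denom == 0:
        logger.info("recall undefined (no truth positives); returning 0")
        return 0.0
    return c.tp / denom


def f1(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


@dataclass
class MetricsReport:
    """Per-slide, per-class, per-stage precision/recall/F1 table."""

    data: pd.DataFrame  # columns: slide, class_name, stage, precision, recall, f1

    def averages(self) -> pd.DataFrame:
        """Unweighted across-slide averages per class and stage."""
        return (
            self.data.groupby(["class_name", "stage"], sort=False)[
                ["precision", "recall", "f1"]
            ]
            .mean()
            .reset_index()
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.data.to_csv(path, index=False, float_format="%.3f")
        return path

    def render_table(self, class_name: str = "periderm") -> str:
        """Plain-text table of one class's scores per slide and stage."""
        lines = []
        sub = self.data[self.data["class_name"] == class_name]
        for slide in sub["slide"].unique():
            lines.append(f"{slide}\tPrecision\tRecall\tF1 score")
            for _, row in sub[sub["slide"] == slide].iterrows():
                lines.append(
                    f"{row['stage']}\t{row['precision']:.3f}\t{row['recall']:.3f}\t{row['f1']:.3f}"
                )
            lines.append("")
        return "\n".join(lines).rstrip() + "\n"


def benchmark_slides(
    pred_masks: dict[str, dict[str, LabelMask]],
    truth_masks: dict[str, LabelMask],
    class_codes: tuple[int, ...] = (1, 2, 3),
) -> MetricsReport:
    """Score predicted masks against truth for several slides.

    ``pred_masks`` maps slide id -> stage name -> mask (stages are
    typically ``before``/``after`` postprocessing); ``truth_masks`` maps
    slide id -> annotation mask. Every predicted slide must have a truth
    mask and vice versa.
    """
    missing = set(pred_masks) ^ set(truth_masks)
    if missing:
        raise ValueError(f"unpaired slide(s): {sorted(missing)}")
    rows = []
    for slide in pred_masks:
        truth = truth_masks[slide]
        for stage, pred in pred_masks[slide].items():
            for code in class_codes:
                c = confusion_counts(pred, truth, code)
                p, r = precision(c), recall(c)
                rows.append(
                    {
                        "slide": slide,
                        "class_name": CLASS_MAP[code],
                        "stage": stage,
                        "precision": p,
                        "recall": r,
                        "f1": f1(p, r),
                    }
                )
    return MetricsReport(pd.DataFrame(rows))
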