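"""Diagnostic metrics: confusion counts, accuracy/sensitivity/specificity,
rank-based AUC, slice-to-scan aggregation, and report tables.

Metrics are reported as percentages by default. AUC is computed by the
tie-aware rank statistic (the probability that a random positive outscores a
random negative, ties counted one half), which equals the area under the
empirical ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import Prediction

__all__ = [
    "ConfusionCounts",
    "MetricsRow",
    "confusion",
    "metrics",
    "auc",
    "scan_level_aggregate",
    "report_table",
    "render_markdown",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must describe at least one example")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRow:
    """One results-table row; ``None`` marks an undefined metric (empty
    class), never silently zero."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None
    model: str = ""


def confusion(predictions: list[Prediction],
              threshold: float = 0.5) -> ConfusionCounts:
    """Threshold probabilities at ``threshold`` (>= is positive) and count."""
    if not predictions:
        raise ValueError("confusion requires at least one prediction")
    tp = fp = tn = fn = 0
    for p in predictions:
        pred = 1 if p.y_hat >= threshold else 0
        if p.y == 1:
            tp += pred
            fn += 1 - pred
        else:
            fp += pred
            tn += 1 - pred
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts, percentage: bool = True,
            model: str = "") -> MetricsRow:
    scale = 100.0 if percentage else 1.0
    accuracy = scale * (c.tp + c.tn) / c.total
    sensitivity = scale * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = scale * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return MetricsRow(accuracy=accuracy, sensitivity=sensitivity,
                      specificity=specificity, model=model)


def auc(predictions: list[Prediction], percentage: bool = False) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y = np.array([p.y for p in predictions])
    s = np.array([p.y_hat for p in predictions])
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(s)
    value = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return float(100.0 * value if percentage else value)


def scan_level_aggregate(slice_predictions: list[Prediction],
                         vote: bool = False,
                         threshold: float = 0.5) -> list[Prediction]:
    """Collapse per-slice predictions to one prediction per scan, keyed by
    the (subject_id, scan_id) provenance prefix.

    Default: mean slice probability. With ``vote``: majority vote over
    thresholded slices (the scan probability is the positive-slice
    fraction).
    """
    groups: dict[tuple, list[Prediction]] = {}
    for p in slice_predictions:
        if len(p.provenance) < 3:
            raise ValueError(
                "slice predictions need (subject, scan, slice) provenance")
        groups.setdefault(tuple(p.provenance[:2]), []).append(p)
    out = []
    for key, preds in groups.items():
        labels = {p.y for p in preds}
        if len(labels) != 1:
            raise ValueError(f"inconsistent labels within scan {key}")
        if vote:
            prob = float(np.mean([p.y_hat >= threshold for p in preds]))
            prob = min(max(prob, 1e-7), 1 - 1e-7)
        else:
            prob = float(np.mean([p.y_hat for p in preds]))
        out.append(Prediction(y=preds[0].y, y_hat=prob, provenance=key))
    return out


def report_table(rows: list[MetricsRow]) -> pd.DataFrame:
    """Results table sorted by ascending accuracy."""
    df = pd.DataFrame([{
        "Model": r.model,
        "Accuracy": r.accuracy,
        "Sensitivity": r.sensitivity,
        "Specificity": r.specificity,
        "AUC": r.auc,
    } for r in rows])
    return df.sort_values("Accuracy", kind="stable").reset_index(drop=True)


def render_markdown(df: pd.DataFrame, decimals: int = 2) -> str:
    """Plain-text Markdown rendering; numbers rounded only at presentation."""
    def fmt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "undefined"
        if isinstance(v, float):
            return f"{v:.{decimals}f}"
        return str(v)

    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(fmt(row[c]) for c in cols) + " |")
    return "\n".join(lines)
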