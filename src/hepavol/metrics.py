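"""Segmentation-quality metrics and per-grade aggregation.

For a predicted mask S and reference mask G (voxel sets):

    Dice      = 100 * 2|S n G| / (|S| + |G|)
    Recall    = 100 * |S n G| / |G|
    Precision = 100 * |S n G| / |S|
    RVD       = 100 * (|S| - |G|) / |G|        (signed)

Dice, precision and recall are reported in percent in [0, 100]; RVD is a
signed percentage (positive = over-segmentation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BinaryMask, require_same_geometry

__all__ = ["SegMetrics", "dice", "recall", "precision", "rvd", "compute_metrics",
           "aggregate_by_grade"]


@dataclass(frozen=True)
class SegMetrics:
    dice_pct: float
    precision_pct: float
    recall_pct: float
    rvd_pct: float


def _counts(S: BinaryMask, G: BinaryMask) -> tuple[int, int, int]:
    require_same_geometry(S, G, "predicted and reference masks")
    s = S.count()
    g = G.count()
    inter = int(np.count_nonzero(S.values & G.values))
    return s, g, inter


def dice(S: BinaryMask, G: BinaryMask) -> float:
    """Dice similarity coefficient in percent.

    Both masks empty is treated as perfect agreement on absence (100, with a
    warning) — the ratio is otherwise undefined.
    """
    s, g, inter = _counts(S, G)
    if s + g == 0:
        warnings.warn("Dice of two empty masks defined as 100 (agreement on absence)")
        return 100.0
    return 100.0 * 2.0 * inter / (s + g)


def recall(S: BinaryMask, G: BinaryMask) -> float:
    """Fraction of the reference captured by the prediction, in percent."""
    s, g, inter = _counts(S, G)
    if g == 0:
        raise ValueError("recall undefined for an empty reference mask")
    return 100.0 * inter / g


def precision(S: BinaryMask, G: BinaryMask) -> float:
    """Fraction of the prediction that is correct, in percent.  An empty
    prediction signals total segmentation failure and is rejected."""
    s, g, inter = _counts(S, G)
    if s == 0:
        raise ValueError("precision undefined for an empty predicted mask")
    return 100.0 * inter / s


def rvd(S: BinaryMask, G: BinaryMask) -> float:
    """Relative volume difference in percent, signed."""
    s, g, _ = _counts(S, G)
    if g == 0:
        raise ValueError("RVD undefined for an empty reference mask")
    return 100.0 * (s - g) / g


def compute_metrics(S: BinaryMask, G: BinaryMask) -> SegMetrics:
    return SegMetrics(
        dice_pct=dice(S, G),
        precision_pct=precision(S, G),
        recall_pct=recall(S, G),
        rvd_pct=rvd(S, G),
    )


def aggregate_by_grade(per_case: list[tuple[SegMetrics, int]]) -> pd.DataFrame:
    """Per-grade and overall mean +/- sample SD of each metric.

    Rows are the grades present (in increasing order) plus an ``overall``
    row; columns carry mean and SD per metric plus the case count ``n``.
    Grades with a single case have undefined sample SD, reported as 0 with
    ``sd_defined`` False.
    """
    if not per_case:
        raise ValueError("aggregate_by_grade requires at least one case")
    rows = [
        {"grade": grade, "dice_pct": m.dice_pct, "precision_pct": m.precision_pct,
         "recall_pct": m.recall_pct, "rvd_pct": m.rvd_pct}
        for m, grade in per_case
    ]
    df = pd.DataFrame(rows)
    cols = ["dice_pct", "precision_pct", "recall_pct", "rvd_pct"]

    def _summarize(sub: pd.DataFrame, label) -> dict:
        out: dict = {"grade": label, "n": len(sub), "sd_defined": len(sub) > 1}
        for c in cols:
            out[f"{c}_mean"] = float(sub[c].mean())
            out[f"{c}_sd"] = float(sub[c].std(ddof=1)) if len(sub) > 1 else 0.0
        return out

    table = [_summarize(sub, grade) for grade, sub in df.groupby("grade", sort=True)]
    table.append(_summarize(df, "overall"))
    return pd.DataFrame(table).set_index("grade")
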