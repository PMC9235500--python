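"""Confusion-matrix metrics and enrichment summaries.

Convention for depletion experiments: a read truly belonging to the
depletion reference and classified for depletion is a true positive; an
off-target (to-be-kept) read flagged for depletion is a false positive.
Zero-denominator ratios are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("no reads evaluated")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return self.__dict__.copy()


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = _ratio(2 * precision * recall, precision + recall) \
        if not (math.isnan(precision) or math.isnan(recall)) else math.nan
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den)
    return MetricsReport(
        accuracy=_ratio(tp + tn, counts.total),
        precision=precision, recall=recall, specificity=specificity,
        f1=f1, mcc=mcc)


def confusion_from_frames(results: pd.DataFrame, truth: pd.DataFrame,
                          positive_class: str = "deplete") -> ConfusionCounts:
    """Join a verdict table (read_id, matched) with truth (read_id,
    true_class) and count the confusion cells."""
    merged = results.merge(truth, on="read_id", how="outer", indicator=True)
    orphans = merged.loc[merged["_merge"] != "both", "read_id"]
    if len(orphans):
        raise ValueError(
            "results/truth mismatch; orphan read ids: "
            + ", ".join(map(str, orphans.head(10))))
    pos = merged["true_class"] == positive_class
    called = merged["matched"].astype(bool)
    return ConfusionCounts(
        tp=int((pos & called).sum()), fp=int((~pos & called).sum()),
        tn=int((~pos & ~called).sum()), fn=int((pos & ~called).sum()))


def enrichment_summary(log: pd.DataFrame) -> pd.DataFrame:
    """Per-class reads / bases / mean / median final read length.

    ``log`` is a session log with ``true_class`` and ``final_length``
    columns (a truth frame may be merged in beforehand).  Totals over rows
    equal the session totals.
    """
    if "true_class" not in log or "final_length" not in log:
        raise ValueError("session log must carry true_class and final_length")
    grouped = log.groupby("true_class")["final_length"]
    out = pd.DataFrame({
        "reads": grouped.size(),
        "bases": grouped.sum(),
        "mean_length": grouped.mean(),
        "median_length": grouped.median(),
    }).reset_index()
    return out.sort_values("true_class", ignore_index=True)
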