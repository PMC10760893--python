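"""Slice-level (2-D) and region-level (3-D) evaluation of scan predictions.

2-D metrics count tampered/real decisions per slice image.  The 3-D protocol
counts per tampered region: a region is a true positive when at least n of
the m consecutive slices containing its central slice are predicted
positive, otherwise a missed report (false negative); each maximal run of at
least n consecutive positive predictions disjoint from every annotated
region counts one false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ScanRule

# Explicit marker for a metric whose denominator is zero.
UNDEFINED = None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never silently as 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    acc = (c.tp + c.tn) / c.total
    p = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else UNDEFINED
    r = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else UNDEFINED
    if p is None or r is None or (p + r) == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * p * r / (p + r)
    return {"accuracy": acc, "precision": p, "recall": r, "f1": f1}


def slice_confusion(predictions, truths) -> ConfusionCounts:
    """Per-slice confusion counts from aligned binary sequences."""
    pred = np.asarray(predictions, dtype=int)
    true = np.asarray(truths, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predictions and truths must be aligned")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )


@dataclass(frozen=True)
class RegionAnnotation:
    """A tampered 3-D region: central slice index and its annotated slice span."""

    scan_id: str
    center_index: int
    span: tuple  # (first_index, last_index), inclusive

    def __post_init__(self):
        lo, hi = self.span
        if not (lo <= self.center_index <= hi):
            raise ValueError("span must contain the central slice")

    def indices(self) -> range:
        return range(self.span[0], self.span[1] + 1)


def _positive_runs(pred: np.ndarray):
    """Maximal runs of consecutive positive predictions as (start, stop) pairs."""
    runs = []
    start = None
    for i, v in enumerate(pred):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(pred)))
    return runs


def region_eval(slice_predictions, annotations, rule: ScanRule = ScanRule()) -> ConfusionCounts:
    """Region-unit confusion counts for one scan's slice predictions.

    For every annotated region, the m-slice window is searched over all
    alignments containing the central slice and the best positive count is
    compared with n.  TP + FN always equals the number of annotations.
    """
    pred = np.asarray(slice_predictions, dtype=int)
    n_slices = pred.size
    tp = fn = 0
    annotated: set[int] = set()
    for ann in annotations:
        if ann.center_index < 0 or ann.center_index >= n_slices:
            raise ValueError(f"annotation center {ann.center_index} outside prediction range")
        if ann.span[0] < 0 or ann.span[1] >= n_slices:
            raise ValueError(f"annotation span {ann.span} outside prediction range")
        annotated.update(ann.indices())
        best = 0
        for start in range(ann.center_index - rule.m + 1, ann.center_index + 1):
            stop = start + rule.m
            if start < 0 or stop > n_slices:
                continue
            best = max(best, int(pred[start:stop].sum()))
        if n_slices < rule.m:  # degenerate short scan: use whole sequence
            best = int(pred.sum())
        if best >= rule.n:
            tp += 1
        else:
            fn += 1
    fp = 0
    for start, stop in _positive_runs(pred):
        if stop - start >= rule.n and not (set(range(start, stop)) & annotated):
            fp += 1
    return ConfusionCounts(tp=tp, tn=0, fp=fp, fn=fn)


def metrics_table(rows: dict) -> pd.DataFrame:
    """Tabulate {scan_id: ConfusionCounts} in the standard report layout."""
    records = []
    for scan_id, counts in rows.items():
        m = confusion_metrics(counts)
        records.append({
            "scan": scan_id, "TP": counts.tp, "TN": counts.tn,
            "FP": counts.fp, "FN": counts.fn,
            "Accuracy": m["accuracy"], "Precision": m["precision"],
            "Recall": m["recall"], "F1-score": m["f1"],
        })
    return pd.DataFrame.from_records(records)
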