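"""Scoring detector calls against the simulation answer key.

The positive class is "truth label is up or down" (direction-agnostic by
default; strict mode additionally requires the called direction to match).
From the 2x2 confusion counts five measures are computed: accuracy,
recall, precision, f-measure and the Matthews correlation coefficient.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import ConfusionCounts, DetectionResult, GroundTruth, MetricSet


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


def confusion_counts(result: DetectionResult, truth: GroundTruth,
                     strict_direction: bool = False) -> ConfusionCounts:
    """TP/TN/FP/FN of one method's calls.

    A detected gene counts as TP when its truth label is up or down; with
    ``strict_direction`` the called direction must also equal the label.
    """
    truth.check_matches(result.table.index)
    labels = truth.label_of.reindex(result.table.index)
    positive = (labels != "none").to_numpy()
    detected = result.table["detected"].to_numpy()
    if strict_direction:
        correct_dir = result.table["direction"].to_numpy() == labels.to_numpy()
        hit = detected & positive & correct_dir
    else:
        hit = detected & positive
    # a wrong-direction call on a shifted gene counts as a miss (FN), not an
    # extra FP, so the four cells always partition the gene set
    tp = int(hit.sum())
    fp = int((detected & ~positive).sum())
    fn = int(positive.sum()) - tp
    tn = int((~positive & ~detected).sum())
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero genes")
    return (c.TP + c.TN) / c.total


def recall(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined without positives")
    return c.TP / (c.TP + c.FN)


def precision(c: ConfusionCounts) -> float:
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined without detections")
    return c.TP / (c.TP + c.FP)


def f_measure(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN), the harmonic mean of precision and recall."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        raise UndefinedMetricError("f-measure undefined: no positives, no calls")
    return 2 * c.TP / denom


def matthews_cc(c: ConfusionCounts) -> tuple[float, bool]:
    """(MCC, degenerate_flag); MCC = 0 when any marginal is empty."""
    marginals = [c.TP + c.FP, c.TP + c.FN, c.TN + c.FP, c.TN + c.FN]
    if any(m == 0 for m in marginals):
        return 0.0, True
    num = c.TP * c.TN - c.FP * c.FN
    return num / math.sqrt(math.prod(marginals)), False


def metric_set(c: ConfusionCounts) -> MetricSet:
    mcc, degenerate = matthews_cc(c)
    return MetricSet(
        acc=accuracy(c),
        rec=recall(c),
        prec=precision(c),
        fm=f_measure(c),
        mcc=mcc,
        degenerate_mcc=degenerate,
    )


def evaluate_method(result: DetectionResult, truth: GroundTruth,
                    strict_direction: bool = False
                    ) -> tuple[ConfusionCounts, MetricSet]:
    c = confusion_counts(result, truth, strict_direction=strict_direction)
    return c, metric_set(c)


def truncate(x: float, digits: int = 3) -> float:
    """Truncate (not round) toward zero at the given decimal place."""
    factor = 10 ** digits
    return math.trunc(x * factor) / factor


def summary_frame(evaluations: dict[str, tuple[ConfusionCounts, MetricSet]],
                  truncate_digits: int | None = None) -> pd.DataFrame:
    """Benchmark-table layout: metric rows, one column per method."""
    rows = ["detected", "TP", "TN", "FP", "FN", "acc", "rec", "prec", "fm", "MCC"]
    out = {}
    for method, (c, m) in evaluations.items():
        vals = [c.detected, c.TP, c.TN, c.FP, c.FN,
                m.acc, m.rec, m.prec, m.fm, m.mcc]
        if truncate_digits is not None:
            vals = vals[:5] + [truncate(v, truncate_digits) for v in vals[5:]]
        out[method] = vals
    return pd.DataFrame(out, index=pd.Index(rows, name="measure"))
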