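"""Cross-method agreement: common calls, Venn partitions, shared false
positives, and an overall per-dataset scoring of methods."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import GroundTruth, InputError, MetricSet

MEASURES = ("acc", "rec", "prec", "fm", "mcc")


@dataclass(frozen=True)
class MethodCallSets:
    """Per-method sets of detected gene ids over a shared gene universe."""

    calls: dict[str, set[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.universe:
            raise InputError("empty gene universe")
        for method, s in self.calls.items():
            extra = s - self.universe
            if extra:
                raise InputError(
                    f"{method} calls {len(extra)} genes outside the universe"
                )

    @classmethod
    def from_results(cls, results: dict[str, "pd.DataFrame | object"]) -> "MethodCallSets":
        """Build from DetectionResult objects (or their tables)."""
        calls, universe = {}, set()
        for method, res in results.items():
            table = res.table if hasattr(res, "table") else res
            calls[method] = set(table.index[table["detected"].astype(bool)])
            universe |= set(table.index)
        return cls(calls=calls, universe=frozenset(universe))


def common_degs(calls: MethodCallSets) -> set[str]:
    """Genes detected by every method (the all-methods Venn region)."""
    if len(calls.calls) < 2:
        raise InputError("need at least two methods for a common-call set")
    sets = iter(calls.calls.values())
    out = set(next(sets))
    for s in sets:
        out &= s
    return out


def venn_partition(calls: MethodCallSets) -> pd.DataFrame:
    """Counts of genes detected by exactly each non-empty method subset.

    One row per membership pattern (columns of 0/1 per method, plus
    ``count``); rows cover all 2^k - 1 non-empty patterns and the counts
    sum to the size of the union of all call sets.
    """
    methods = list(calls.calls)
    if not 1 <= len(methods) <= 6:
        raise InputError("venn partition supports 1-6 methods")
    pattern_counts: dict[tuple[int, ...], int] = {}
    union = set().union(*calls.calls.values())
    for gene in union:
        pattern = tuple(int(gene in calls.calls[m]) for m in methods)
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
    rows = []
    for mask in range(1, 2 ** len(methods)):
        pattern = tuple((mask >> i) & 1 for i in range(len(methods)))
        rows.append({**dict(zip(methods, pattern)),
                     "count": pattern_counts.get(pattern, 0)})
    return pd.DataFrame(rows)


def excess_crosstab(calls: MethodCallSets, truth: GroundTruth) -> pd.DataFrame:
    """False positives of each method grouped by which other methods agree.

    For every method with at least one false positive, its FP genes are
    grouped by the yes/no pattern of detection by the OTHER methods; one
    row per (method, pattern) with the count of genes sharing it.  Methods
    without false positives are omitted.
    """
    truth.check_matches(sorted(calls.universe))
    positives = set(truth.positives())
    methods = list(calls.calls)
    rows = []
    for method in methods:
        fps = calls.calls[method] - positives
        if not fps:
            continue
        patterns: dict[tuple[str, ...], int] = {}
        for gene in sorted(fps):
            pat = tuple(
                "-" if m == method else ("Yes" if gene in calls.calls[m] else "No")
                for m in methods
            )
            patterns[pat] = patterns.get(pat, 0) + 1
        for pat, count in sorted(patterns.items(),
                                 key=lambda kv: (-sum(p == "Yes" for p in kv[0]),
                                                 kv[0])):
            rows.append({"method": method, "excess": count,
                         **dict(zip(methods, pat))})
    return pd.DataFrame(rows, columns=["method", "excess", *methods])


def _points_for_dataset(metrics: dict[str, MetricSet], near: float = 0.02) -> dict[str, int]:
    table = pd.DataFrame({m: ms.as_dict() for m, ms in metrics.items()})
    best = table.max(axis=1)
    worst = table.min(axis=1)
    points = {}
    for method in table.columns:
        col = table[method]
        n_best = int((col >= best).sum())
        n_worst = int((col <= worst).sum())
        n_near = int((col >= best - near).sum())
        if n_best >= 3:
            points[method] = 3
        elif n_worst >= 3:
            points[method] = 0
        elif n_best >= 1 or n_near >= 3:
            points[method] = 2
        else:
            points[method] = 1
    return points


def overall_score(per_dataset_metrics: dict[str, dict[str, MetricSet]],
                  near: float = 0.02) -> pd.DataFrame:
    """Tiered plus-point scores per method and dataset, plus totals.

    Per dataset a method earns 3 points when best (or tied best) on at
    least three of the five measures; 0 when worst on at least three; 2
    when best on at least one measure or within ``near`` of best on at
    least three; otherwise 1 (mid-field).  The overall score sums over
    datasets.  The tiering is a documented convention, not a canonical
    statistic — adjust ``near`` to taste.
    """
    if not per_dataset_metrics:
        raise InputError("need at least one dataset")
    methods = None
    rows = {}
    for dataset, metrics in per_dataset_metrics.items():
        if not metrics:
            raise InputError(f"dataset {dataset!r} has no method metrics")
        if methods is None:
            methods = list(metrics)
        elif set(methods) != set(metrics):
            raise InputError("datasets score different method sets")
        rows[dataset] = _points_for_dataset(metrics, near=near)
    out = pd.DataFrame(rows).T[methods]
    out.loc["overall"] = out.sum(axis=0)
    out.index.name = "dataset"
    return out
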