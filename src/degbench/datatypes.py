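"""Core containers shared across the benchmark.

An :class:`ExpressionSet` is a genes x samples matrix of (log-scale)
expression values together with a two-group sample assignment.  A
:class:`GroundTruth` is the simulation answer key: each gene is labelled
``none``, ``up`` or ``down``.  Detectors return a :class:`DetectionResult`;
scoring produces :class:`ConfusionCounts` and a :class:`MetricSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

TRUTH_LABELS = ("none", "up", "down")


class InputError(ValueError):
    """Malformed or inconsistent user input (files, matrices, group maps)."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


@dataclass(frozen=True)
class ExpressionSet:
    """Two-group expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    groups
        Series mapping sample id -> group label; exactly two labels, each
        with at least two samples for most detectors (rank products accepts
        one).
    control
        Which group plays the reference role in fold changes.  Defaults to
        ``"control"`` when present, otherwise the alphabetically first label.
    """

    values: pd.DataFrame
    groups: pd.Series
    control: str = field(default="")

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise InputError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene ids: {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise InputError(f"samples absent from group map: {missing}")
        labels = sorted(set(self.groups.loc[self.values.columns]))
        if len(labels) != 2:
            raise InputError(f"expected exactly two groups, found {labels}")
        if not self.control:
            object.__setattr__(
                self, "control", "control" if "control" in labels else labels[0]
            )
        elif self.control not in labels:
            raise InputError(f"control group {self.control!r} not among {labels}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def treatment(self) -> str:
        labels = set(self.groups.loc[self.values.columns])
        return next(iter(labels - {self.control}))

    def group_matrix(self, group: str) -> np.ndarray:
        """Values of one group as a dense (genes, samples) array."""
        cols = [s for s in self.values.columns if self.groups[s] == group]
        return self.values[cols].to_numpy(dtype=float)

    def control_matrix(self) -> np.ndarray:
        return self.group_matrix(self.control)

    def treatment_matrix(self) -> np.ndarray:
        return self.group_matrix(self.treatment)


@dataclass(frozen=True)
class GroundTruth:
    """Per-gene answer key with labels in {none, up, down}."""

    label_of: pd.Series

    def __post_init__(self) -> None:
        bad = set(self.label_of.unique()) - set(TRUTH_LABELS)
        if bad:
            raise InputError(f"unknown truth labels: {sorted(bad)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.label_of.index

    @property
    def n_positive(self) -> int:
        return int((self.label_of != "none").sum())

    def positives(self) -> pd.Index:
        return self.label_of.index[self.label_of != "none"]

    def check_matches(self, gene_ids) -> None:
        mine, theirs = set(self.label_of.index), set(gene_ids)
        if mine != theirs:
            offending = sorted(mine ^ theirs)
            raise InputError(
                f"gene sets differ; {len(offending)} offending ids, "
                f"e.g. {offending[:5]}"
            )


@dataclass(frozen=True)
class DetectionResult:
    """One detector's verdict on every gene.

    ``table`` has columns ``gene_id`` (index), ``statistic``, ``p_value``
    (NaN where the method has no p-value), ``fold_change``, ``direction``
    and boolean ``detected``; extra method-specific columns (e.g. rank
    product's ``pfp``) may follow.
    """

    method: str
    table: pd.DataFrame
    params_used: Mapping[str, object]

    def __post_init__(self) -> None:
        required = {"statistic", "p_value", "fold_change", "direction", "detected"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"result table missing columns {sorted(missing)}")

    @property
    def detected_ids(self) -> set[str]:
        return set(self.table.index[self.table["detected"]])


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def detected(self) -> int:
        """Number of detected genes (the tables' 'number of detected values')."""
        return self.TP + self.FP


@dataclass(frozen=True)
class MetricSet:
    acc: float
    rec: float
    prec: float
    fm: float
    mcc: float
    degenerate_mcc: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "acc": self.acc,
            "rec": self.rec,
            "prec": self.prec,
            "fm": self.fm,
            "mcc": self.mcc,
        }
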