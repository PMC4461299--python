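"""Shared detector machinery: parameters, fold changes, result assembly."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ..datatypes import ConfigurationError, DetectionResult, ExpressionSet, InputError

METHODS = ("SAM", "RP", "BA", "MW", "TT", "LIMMA")

#: Benchmark defaults: raw significance thresholds per method, and the
#: fold-change cut for SAM (ratio scale; 2.00 means |log2 fc| >= 1 on
#: log-scale data).  No multiplicity correction is applied by default —
#: these are raw per-gene thresholds.
DEFAULT_ALPHA = {"TT": 0.01, "MW": 0.05, "BA": 0.02, "RP": 0.01, "LIMMA": 0.05,
                 "SAM": 0.05}
DEFAULT_PERMUTATIONS = {"SAM": 200, "RP": 100}


@dataclass(frozen=True)
class MethodParams:
    """Tuning knobs of one detector.

    ``alpha`` is the raw p-value threshold (for SAM it is the q-value
    threshold applied to permutation p-values).  ``fold_change_threshold``
    is on the ratio scale; with ``fc_scale='log2'`` (the default, matching
    log-like input values) a threshold of 2.0 means |mean difference| >= 1.
    ``n_permutations`` only matters for SAM and RP.
    """

    method: str
    alpha: float = field(default=None)  # type: ignore[assignment]
    fold_change_threshold: float = 2.0
    n_permutations: int = field(default=None)  # type: ignore[assignment]
    seed: int = 0
    fc_scale: str = "log2"  # or "linear"
    welch: bool = True  # TT only: unequal-variance form

    def __post_init__(self) -> None:
        m = self.method.upper()
        if m not in METHODS:
            raise ConfigurationError(f"unknown method {self.method!r}")
        object.__setattr__(self, "method", m)
        if self.alpha is None:
            object.__setattr__(self, "alpha", DEFAULT_ALPHA[m])
        if self.n_permutations is None:
            object.__setattr__(self, "n_permutations", DEFAULT_PERMUTATIONS.get(m, 100))
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.fold_change_threshold < 1:
            raise ConfigurationError("fold_change_threshold must be >= 1")
        if self.n_permutations < 10:
            raise ConfigurationError("need at least 10 permutations")
        if self.fc_scale not in ("log2", "linear"):
            raise ConfigurationError("fc_scale must be 'log2' or 'linear'")


def group_arrays(expr: ExpressionSet) -> tuple[np.ndarray, np.ndarray]:
    """(control, treatment) matrices; errors on an empty group."""
    xc, xt = expr.control_matrix(), expr.treatment_matrix()
    if xc.shape[1] == 0 or xt.shape[1] == 0:
        raise InputError("each group needs at least one sample")
    return xc, xt


def fold_change(expr: ExpressionSet) -> pd.Series:
    """Signed mean difference treatment - control per gene (log-like scale)."""
    xc, xt = group_arrays(expr)
    return pd.Series(xt.mean(axis=1) - xc.mean(axis=1), index=expr.gene_ids,
                     name="fold_change")


def fold_change_mask(fc: np.ndarray, expr: ExpressionSet,
                     params: MethodParams) -> np.ndarray:
    """Genes passing the fold-change filter under the configured scale."""
    if params.fc_scale == "log2":
        return np.abs(fc) >= np.log2(params.fold_change_threshold)
    # linear: values are unlogged intensities; compare group-mean ratios
    xc, xt = group_arrays(expr)
    mc, mt = xc.mean(axis=1), xt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mc != 0, mt / mc, np.inf)
    t = params.fold_change_threshold
    return (ratio >= t) | (ratio <= 1 / t)


def directions(fc: np.ndarray) -> np.ndarray:
    out = np.where(fc > 0, "up", np.where(fc < 0, "down", "none"))
    return out.astype(object)


def assemble(method: str, expr: ExpressionSet, statistic, p_value, fc,
             detected, params: MethodParams, **extra) -> DetectionResult:
    table = pd.DataFrame(
        {
            "statistic": np.asarray(statistic, dtype=float),
            "p_value": np.asarray(p_value, dtype=float),
            "fold_change": np.asarray(fc, dtype=float),
            "direction": directions(np.asarray(fc)),
            "detected": np.asarray(detected, dtype=bool),
        },
        index=expr.gene_ids,
    )
    for name, col in extra.items():
        table[name] = col
    return DetectionResult(method=method, table=table, params_used=asdict(params))


def permutation_seed(params: MethodParams) -> np.random.Generator:
    """Per-method generator derived from (seed, method) so streams differ."""
    idx = METHODS.index(params.method)
    ss = np.random.SeedSequence(entropy=int(params.seed) % 2**31, spawn_key=(idx,))
    return np.random.default_rng(ss)
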