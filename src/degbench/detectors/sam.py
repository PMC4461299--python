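"""Significance-analysis relative-difference statistic with permutation null.

The statistic for gene g is the relative difference

    d_g = (mean_treat - mean_ctrl) / (s_g + s0)

where s_g is the gene's pooled standard error and s0 ("fudge factor") is an
additive offset that stops low-variance genes from dominating.  s0 is chosen
among percentiles of the s_g distribution to make the spread of d as
independent of s as possible (minimum coefficient of variation of windowed
median absolute deviations).  Significance comes from a group-label
permutation null pooled across genes; genes are called when their
Benjamini-Hochberg q-value passes the threshold AND their fold change
passes the configured cut.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ..datatypes import DetectionResult, ExpressionSet, InputError
from .base import MethodParams, assemble, fold_change_mask, group_arrays, permutation_seed

log = logging.getLogger(__name__)


def relative_difference(xt: np.ndarray, xc: np.ndarray,
                        s0: float) -> tuple[np.ndarray, np.ndarray]:
    """(d, s): the relative difference and pooled standard error per gene."""
    n1, n2 = xt.shape[1], xc.shape[1]
    fc = xt.mean(axis=1) - xc.mean(axis=1)
    pooled = (
        ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ) / (n1 + n2 - 2)
    s = np.sqrt((1 / n1 + 1 / n2) * pooled)
    return fc / (s + s0), s


def choose_s0(xt: np.ndarray, xc: np.ndarray, n_windows: int = 100) -> float:
    """Fudge factor minimizing the CV of windowed MADs of d across s.

    Candidates are the 0th, 5th, ..., 100th percentiles of {s_g}; for each,
    genes are split into quantile windows of s and the candidate whose
    windowed MAD(d) values have the smallest coefficient of variation wins.
    """
    _, s = relative_difference(xt, xc, 0.0)
    g = s.size
    n_windows = min(n_windows, max(2, g // 10))
    order = np.argsort(s, kind="stable")
    windows = np.array_split(order, n_windows)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d, _ = relative_difference(xt, xc, s0)
        v = np.array([stats.median_abs_deviation(d[w], scale="normal")
                      for w in windows])
        mean_v = v.mean()
        if mean_v == 0:
            continue
        cv = v.std(ddof=1) / mean_v
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _label_permutations(n1: int, n2: int, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(B, n1) index arrays choosing the permuted treatment columns."""
    n = n1 + n2
    total = comb(n, n1)
    if total <= n_perm:
        log.warning("only %d distinct label assignments; enumerating all", total)
        return np.array([c for c in combinations(range(n), n1)])
    out = np.empty((n_perm, n1), dtype=int)
    for b in range(n_perm):
        out[b] = rng.permutation(n)[:n1]
    return out


def detect_sam(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Relative-difference detector; q <= alpha and fold-change filter."""
    xc, xt = group_arrays(expr)
    if xc.shape[1] < 2 or xt.shape[1] < 2:
        raise InputError("the relative-difference statistic needs >= 2 samples per group")
    n1, n2 = xt.shape[1], xc.shape[1]
    s0 = choose_s0(xt, xc)
    d, s = relative_difference(xt, xc, s0)

    rng = permutation_seed(params)
    combined = np.hstack([xt, xc])
    perms = _label_permutations(n1, n2, params.n_permutations, rng)
    null = np.empty((len(perms), d.size))
    all_cols = np.arange(n1 + n2)
    for b, treat_cols in enumerate(perms):
        ctrl_cols = np.setdiff1d(all_cols, treat_cols)
        null[b], _ = relative_difference(combined[:, treat_cols],
                                         combined[:, ctrl_cols], s0)
    # pooled permutation null across genes and permutations
    pool = np.sort(np.abs(null).ravel())
    exceed = pool.size - np.searchsorted(pool, np.abs(d), side="left")
    p = (1 + exceed) / (1 + pool.size)
    q = multipletests(p, method="fdr_bh")[1]

    fc = xt.mean(axis=1) - xc.mean(axis=1)
    detected = (q <= params.alpha) & fold_change_mask(fc, expr, params)
    return assemble("SAM", expr, d, p, fc, detected, params,
                    q_value=q, s0=np.full_like(d, s0))
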