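"""Rank-product detector with a permutation null over rank assignments.

For every treatment/control sample pair (k of K = n1*n2), the gene-wise
pairwise differences are ranked across genes: rank 1 is the most positive
difference in the up-regulation search, the most negative in the
down-regulation search.  The rank product of gene g is the geometric mean
of its ranks over the K pairs; consistently extreme genes have rank
products near 1.  Significance comes from the standard permutation scheme:
each of B rounds assigns every comparison an independent uniform random
permutation of ranks, and the null rank products of all genes are pooled,
giving per-gene p-values (and percentage-of-false-prediction values) for
each direction.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..datatypes import DetectionResult, ExpressionSet, InputError
from .base import MethodParams, assemble, group_arrays, permutation_seed


def _log_rank_products(diffs: np.ndarray, descending: bool) -> np.ndarray:
    """Mean log rank per gene; diffs is (genes, comparisons)."""
    x = -diffs if descending else diffs
    ranks = stats.rankdata(x, axis=0, method="average")
    return np.log(ranks).mean(axis=1)


def detect_rp(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Two one-sided rank-product searches; detected iff min p < alpha."""
    xc, xt = group_arrays(expr)
    g = xc.shape[0]
    if g == 0:
        raise InputError("empty expression matrix")
    n1, n2 = xt.shape[1], xc.shape[1]
    k = n1 * n2
    # pairwise differences, one column per (treatment, control) sample pair
    diffs = (xt[:, :, None] - xc[:, None, :]).reshape(g, k)
    log_up = _log_rank_products(diffs, descending=True)
    log_down = _log_rank_products(diffs, descending=False)

    rng = permutation_seed(params)
    b = params.n_permutations
    base = np.broadcast_to(np.arange(1, g + 1, dtype=float), (k, g))
    null = np.empty((b, g))
    for i in range(b):
        ranks = rng.permuted(base, axis=1)  # independent uniform ranks per pair
        null[i] = np.log(ranks).mean(axis=0)
    pool = np.sort(null.ravel())

    def pvals(log_rp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = np.searchsorted(pool, log_rp, side="right")  # null RPs <= observed
        p = (1 + c) / (1 + pool.size)
        expected_fp = c / b
        order_rank = stats.rankdata(log_rp, method="average")
        pfp = np.minimum(expected_fp / order_rank, 1.0)
        return p, pfp

    p_up, pfp_up = pvals(log_up)
    p_down, pfp_down = pvals(log_down)

    up_wins = p_up <= p_down
    p = np.where(up_wins, p_up, p_down)
    pfp = np.where(up_wins, pfp_up, pfp_down)
    rp = np.exp(np.where(up_wins, log_up, log_down))
    fc = xt.mean(axis=1) - xc.mean(axis=1)
    detected = p < params.alpha
    result = assemble("RP", expr, rp, p, fc, detected, params, pfp=pfp,
                      rp_up=np.exp(log_up), rp_down=np.exp(log_down))
    # direction follows the better-supported search, not the raw mean difference
    table = result.table
    table["direction"] = np.where(up_wins, "up", "down")
    table.loc[(p_up == p_down) & (fc == 0) & ~detected, "direction"] = "none"
    return result
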