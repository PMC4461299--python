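"""Gene-wise two-sample tests: Student/Welch t, Mann-Whitney, Bland-Altman.

The t-test and Mann-Whitney test each gene in isolation.  Bland-Altman is
different in kind: it standardizes each gene's mean difference against the
across-gene spread of differences and flags genes outside the limits of
agreement, so the whole expression matrix acts as its own null ensemble.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ..datatypes import DetectionResult, ExpressionSet, InputError
from .base import MethodParams, assemble, group_arrays

log = logging.getLogger(__name__)


def detect_tt(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Two-sample t-test per gene, two-sided, detected iff p < alpha.

    Welch's unequal-variance form by default (``params.welch=False`` for
    the pooled-variance form).  Genes that are constant and identical in
    both groups get t = 0, p = 1 rather than an error.
    """
    xc, xt = group_arrays(expr)
    if xc.shape[1] < 2 or xt.shape[1] < 2:
        raise InputError("t-test needs at least two samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xt, xc, axis=1, equal_var=not params.welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: equal means -> no evidence (p = 1)
    nan = ~np.isfinite(p)
    t[nan] = 0.0
    p[nan] = 1.0
    fc = xt.mean(axis=1) - xc.mean(axis=1)
    return assemble("TT", expr, t, p, fc, p < params.alpha, params)


def detect_mw(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Two-sided Mann-Whitney rank-sum test per gene.

    Uses the exact null distribution when both groups have <= 8 samples and
    the gene has no ties; otherwise the normal approximation with tie and
    continuity correction.  Genes whose values are all tied get p = 1.
    """
    xc, xt = group_arrays(expr)
    if xc.shape[1] < 2 or xt.shape[1] < 2:
        raise InputError("Mann-Whitney needs at least two samples per group")
    n1, n2 = xt.shape[1], xc.shape[1]
    g = xc.shape[0]
    u = np.empty(g)
    p = np.empty(g)

    combined = np.sort(np.hstack([xt, xc]), axis=1)
    has_ties = (np.diff(combined, axis=1) == 0).any(axis=1)
    exact_ok = n1 <= 8 and n2 <= 8

    def run(mask: np.ndarray, method: str) -> None:
        if not mask.any():
            return
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.mannwhitneyu(
                xt[mask], xc[mask], axis=1, alternative="two-sided", method=method
            )
        u[mask] = res.statistic
        p[mask] = res.pvalue

    if exact_ok:
        run(~has_ties, "exact")
        run(has_ties, "asymptotic")
    else:
        run(np.ones(g, dtype=bool), "asymptotic")

    all_tied = combined[:, 0] == combined[:, -1]
    p[all_tied | ~np.isfinite(p)] = 1.0
    np.clip(p, None, 1.0, out=p)
    fc = xt.mean(axis=1) - xc.mean(axis=1)
    return assemble("MW", expr, u, p, fc, p < params.alpha, params)


def detect_ba(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Bland-Altman limits of agreement across genes.

    For gene g let d_g be its mean difference (treatment - control) and m, s
    the mean and SD of d over all genes.  z_g = (d_g - m)/s is referred to
    the standard normal; a gene is discordant — detected — iff its two-sided
    tail probability is below alpha, i.e. d_g falls outside
    m +/- z_{1-alpha/2} * s.
    """
    xc, xt = group_arrays(expr)
    if xc.shape[0] < 3:
        raise InputError("Bland-Altman needs at least three genes")
    d = xt.mean(axis=1) - xc.mean(axis=1)
    m, s = d.mean(), d.std(ddof=1)
    if s == 0:
        log.warning("Bland-Altman: zero spread of differences; nothing detected")
        z = np.zeros_like(d)
        p = np.ones_like(d)
    else:
        z = (d - m) / s
        p = 2 * stats.norm.sf(np.abs(z))
        p = np.maximum(p, np.finfo(float).tiny)
    mean_level = (xt.mean(axis=1) + xc.mean(axis=1)) / 2
    return assemble("BA", expr, z, p, d, p < params.alpha, params,
                    mean_level=mean_level)
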