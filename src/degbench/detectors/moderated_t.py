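"""Empirical-Bayes moderated t-statistic for two-group designs.

Each gene is fit as a two-group linear model, giving a residual variance
s_g^2 on d_g = n1 + n2 - 2 degrees of freedom.  The ensemble of variances
is assumed to follow a scaled inverse-chi-square prior with hyperparameters
(d0, s0^2), estimated by moment-matching the log-variance distribution
(digamma/trigamma matching).  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t-statistic, which then has d0 + d_g degrees of
freedom.  Shrinking unstable gene-wise variances toward the pooled prior is
what lets the method keep power at small replicate numbers.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import special, stats

from ..datatypes import DetectionResult, ExpressionSet, InputError
from .base import MethodParams, assemble, group_arrays

log = logging.getLogger(__name__)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is convex and decreasing on (0, inf); the iteration below (in
    1/x to keep steps stable) converges from the asymptotic start x ~ 1/y.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 for x -> 0
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Hyperparameters (d0, s0^2) of the inverse-chi-square variance prior.

    Matches mean and variance of log(s_g^2) to their theoretical values
    under the hierarchical model.  Returns d0 = inf (complete pooling at
    the geometric-mean variance) when the observed log-variance spread does
    not exceed the chi-square sampling noise.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive gene variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        # no excess spread beyond chi-square noise: complete pooling at the
        # ordinary pooled variance, so a constant ensemble stays untouched
        return np.inf, float(s2.mean())
    d0 = 2 * _trigamma_inverse(evar)
    s0_sq = np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2))
    return float(d0), float(s0_sq)


def detect_limma(expr: ExpressionSet, params: MethodParams) -> DetectionResult:
    """Moderated t per gene; detected iff the two-sided p-value < alpha."""
    xc, xt = group_arrays(expr)
    n1, n2 = xt.shape[1], xc.shape[1]
    if n1 < 2 or n2 < 2:
        raise InputError("moderated t needs at least two samples per group")
    if xc.shape[0] < 50:
        log.warning(
            "moderated t with %d genes: empirical-Bayes pooling is unreliable "
            "on small ensembles", xc.shape[0],
        )
    df = n1 + n2 - 2
    rss = ((xt - xt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xc - xc.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = rss / df
    try:
        d0, s0_sq = estimate_prior(s2, df)
    except ValueError:
        d0, s0_sq = np.inf, float(s2.mean())
        log.warning("variance-prior estimation failed; pooling all variances")
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    fc = xt.mean(axis=1) - xc.mean(axis=1)
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return assemble("LIMMA", expr, t, p, fc, p < params.alpha, params,
                    posterior_sd=np.sqrt(s2_post))
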