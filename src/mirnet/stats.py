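"""Shared statistical machinery.

Benjamini-Hochberg step-up adjustment with missing-value propagation and
the empirical-Bayes variance moderation used by both array analyses: the
per-feature sample variances are modelled as scaled-F draws around a
prior variance ``s0_sq`` with ``d0`` prior degrees of freedom, the
hyperparameters are estimated by moment matching on the log variances
(digamma/trigamma equations), and each feature's variance is shrunk to
the weighted combination ``(d0*s0_sq + d*s2) / (d0 + d)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "bh_adjust",
    "EBayesParams",
    "trigamma_inverse",
    "fit_scaled_f",
    "squeeze_variances",
    "moderated_t",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries (NaN) propagate as missing and are excluded from the
    number of tests ``m``. Values outside [0, 1] are rejected.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    if ps.size and (ps.min() < 0 or ps.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class EBayesParams:
    """Hyperparameters of the scaled-F prior on feature variances."""

    d0: float  # prior degrees of freedom; 0 disables shrinkage, inf pools fully
    s0_sq: float = 1.0  # prior variance (ignored when d0 == 0)

    def __post_init__(self) -> None:
        if np.isnan(self.d0) or self.d0 < 0:
            raise ValueError("d0 must be non-negative")
        if self.d0 > 0 and not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 75) -> float:
    """Solve ``trigamma(y) = x`` for ``y > 0`` by Newton iteration."""
    if not np.isfinite(x) or x <= 0:
        raise ValueError("trigamma_inverse requires a positive finite argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            return float(y)
    raise RuntimeError("trigamma inversion did not converge")


def fit_scaled_f(s2, df) -> EBayesParams:
    """Estimate (d0, s0_sq) by moment matching on log sample variances.

    ``e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2)`` is an unbiased
    estimate of ``log(sigma2_g)``; the mean and excess variance of the
    ``e_g`` identify the prior via digamma/trigamma equations. A
    non-positive excess variance, or a failed trigamma inversion, falls
    back to complete pooling (``d0 = inf``) with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & np.isfinite(df) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances with positive df")
    s2u, dfu = s2[ok], df[ok]
    z = np.log(s2u)
    e = z - special.digamma(dfu / 2.0) + np.log(dfu / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, dfu / 2.0))
    if evar > 0:
        try:
            d0 = 2.0 * trigamma_inverse(evar)
            s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            return EBayesParams(d0=float(d0), s0_sq=s0_sq)
        except (ValueError, RuntimeError):
            warnings.warn("trigamma inversion failed; falling back to d0 = inf (complete pooling)")
    return EBayesParams(d0=np.inf, s0_sq=float(np.exp(emean)))


def squeeze_variances(s2, df, params: EBayesParams) -> np.ndarray:
    """Posterior (shrunk) variances under the scaled-F prior."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(params.d0):
        return np.full(s2.shape, params.s0_sq)
    if params.d0 == 0:
        return s2.copy()
    return (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)


def moderated_t(coef, stdev_unscaled, s2, df, params: EBayesParams | None = None):
    """Moderated t-statistics from per-feature linear-model summaries.

    Parameters
    ----------
    coef : effect estimates per feature.
    stdev_unscaled : design-dependent unscaled SE (SE = sqrt(s2) * u).
    s2 : residual variances per feature.
    df : residual degrees of freedom per feature.
    params : prior hyperparameters; estimated from (s2, df) when None.
        ``d0 = 0`` gives the ordinary t, ``d0 = inf`` the fully pooled z.

    Returns
    -------
    (t, p, df_total, params): arrays of moderated t, two-sided p, total
    degrees of freedom, and the hyperparameters used.
    """
    coef = np.asarray(coef, dtype=float)
    u = np.asarray(stdev_unscaled, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).astype(float)
    if params is None:
        params = fit_scaled_f(s2, df)
    if params.d0 == 0:
        s2_post = s2.copy()
        df_total = df.copy()
    else:
        s2_post = squeeze_variances(s2, df, params)
        df_total = df + params.d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (np.sqrt(s2_post) * u)
    p = np.full(t.shape, np.nan)
    finite = np.isfinite(t)
    norm_df = finite & np.isinf(df_total)
    t_df = finite & ~np.isinf(df_total)
    p[norm_df] = 2.0 * stats.norm.sf(np.abs(t[norm_df]))
    p[t_df] = 2.0 * stats.t.sf(np.abs(t[t_df]), df_total[t_df])
    return t, p, df_total, params
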