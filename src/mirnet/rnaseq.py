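"""Count-based two-group differential expression.

The workflow mirrors the standard negative-binomial analysis of bulk
RNA-seq counts: median-of-ratios size factors, a method-of-moments
dispersion estimate per gene shrunk toward a fitted mean-dispersion
trend ``alpha(mu) = a0 + a1/mu``, and a per-gene NB Wald test of the
two-group effect with BH adjustment. Genes are called significant at
adjusted p < 0.1 by default.

The per-gene NB fit with known dispersion is solved by a vectorized
Newton iteration on the group means (the two-group log-link model is
separable by group), and the Wald standard error comes from the observed
information at the MLE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .report import FilterChain
from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_de",
    "NegativeBinomialWaldDE",
]

LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Integer gene x sample count table with per-sample metadata.

    ``samples`` must be indexed by the column labels of ``values`` and
    carry at least a ``group`` column with the two condition labels;
    ``pool`` and ``region`` columns are carried through when present.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        vals = self.values.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata needs a 'group' column")
        groups = self.samples.loc[self.values.columns, "group"]
        if groups.nunique() != 2:
            raise ValueError("exactly two groups are required")

    def group_indicator(self, case: str = "MSA") -> np.ndarray:
        """0/1 indicator per sample column; 1 marks the case group."""
        groups = self.samples.loc[self.values.columns, "group"]
        labels = sorted(groups.unique())
        if case in labels:
            return (groups == case).to_numpy(dtype=int)
        # fall back to the lexicographically later label as the case group
        return (groups == labels[-1]).to_numpy(dtype=int)


def estimate_size_factors(counts, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference per gene is its geometric mean across samples, using
    only genes with all-positive counts; each sample's factor is the
    median of its count/reference ratios. When no gene is positive in
    every sample, an error instructs to set ``pseudo_reference=True``,
    which computes the reference over the positive entries of each gene
    instead.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    x = values.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        geomean = np.exp(np.log(x[all_pos]).mean(axis=1))
        ratios = x[all_pos] / geomean[:, None]
    elif pseudo_reference:
        pos = x > 0
        usable = pos.any(axis=1)
        if not usable.any():
            raise ValueError("all counts are zero")
        with np.errstate(divide="ignore"):
            logx = np.where(pos, np.log(np.where(pos, x, 1.0)), np.nan)[usable]
        geomean = np.exp(np.nanmean(logx, axis=1))
        ratios = np.where(pos[usable], x[usable] / geomean[:, None], np.nan)
    else:
        raise ValueError(
            "no gene has positive counts in every sample; "
            "set pseudo_reference=True to use a positive-count reference"
        )
    with np.errstate(invalid="ignore"):
        sf = np.nanmedian(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))  # geometric mean 1
    return pd.Series(sf, index=values.columns, name="size_factor")


def _fit_trend(alpha_hat: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Robust fit of alpha(mu) = a0 + a1/mu over genes with signal."""
    import statsmodels.api as sm

    ok = np.isfinite(alpha_hat) & np.isfinite(mu) & (mu > 0)
    use = ok & (alpha_hat > 0)
    if use.sum() < 10:  # too little overdispersion to anchor a trend
        return 0.0, 0.0
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    try:
        fit = sm.RLM(alpha_hat[use], X, M=sm.robust.norms.HuberT()).fit()
        a0, a1 = fit.params
    except Exception:
        a0, a1 = np.linalg.lstsq(X, alpha_hat[use], rcond=None)[0]
    return float(max(a0, 0.0)), float(max(a1, 0.0))


def estimate_dispersions(counts, size_factors: pd.Series, shrink_weight: float = 0.5) -> pd.DataFrame:
    """Gene-wise NB dispersions with trend shrinkage.

    Method of moments on size-factor-normalized counts pooled within
    groups: with q = y/s, Var(q) = mu*mean(1/s) + alpha*mu^2 per group,
    so ``alpha_hat = max(0, (pooled var - mean(1/s)*mu) / mu^2)``. The
    gene estimates are then shrunk by ``shrink_weight`` toward the
    robust trend ``alpha(mu) = a0 + a1/mu``.

    Returns a DataFrame with columns ``alpha`` (final), ``alpha_gene``
    (raw MoM), ``trend`` and ``base_mean``; trend coefficients are in
    ``.attrs['trend_coef']``.
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    if cm is None:
        raise TypeError("estimate_dispersions expects a CountMatrix")
    if not 0.0 <= shrink_weight <= 1.0:
        raise ValueError("shrink_weight must be in [0, 1]")
    x = cm.values.to_numpy(dtype=float)
    s = size_factors.loc[cm.values.columns].to_numpy(dtype=float)
    ind = cm.group_indicator()
    q = x / s
    num = 0.0
    den = 0
    for g in (0, 1):
        cols = ind == g
        if cols.sum() < 2:
            raise ValueError("each group needs at least two samples")
        qg = q[:, cols]
        vg = qg.var(axis=1, ddof=1)
        mg = qg.mean(axis=1)
        inv_s = np.mean(1.0 / s[cols])
        num = num + (cols.sum() - 1) * (vg - inv_s * mg)
        den += cols.sum() - 1
    mu = q.mean(axis=1)
    pooled_excess = num / den
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = np.where(mu > 0, pooled_excess / np.maximum(mu, 1e-300) ** 2, 0.0)
    alpha_gene = np.maximum(alpha_gene, 0.0)
    a0, a1 = _fit_trend(alpha_gene, mu)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / np.maximum(mu, 1e-300), 0.0)
    alpha = (1.0 - shrink_weight) * alpha_gene + shrink_weight * trend
    out = pd.DataFrame(
        {"alpha": alpha, "alpha_gene": alpha_gene, "trend": trend, "base_mean": mu},
        index=cm.values.index,
    )
    out.attrs["trend_coef"] = (a0, a1)
    return out


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """MLE of the per-gene group mean m in NB(s_j * m, alpha).

    Solves sum_j (y_j - s_j m) / (1 + alpha s_j m) = 0 by Newton
    iteration, vectorized over genes. alpha = 0 reduces to the closed
    form sum(y)/sum(s).
    """
    alpha = np.asarray(alpha, dtype=float)
    total = y.sum(axis=1)
    mk = total / s.sum()  # closed form; exact for alpha = 0, start value otherwise
    active = (alpha > 0) & (total > 0)
    for _ in range(max_iter):
        if not active.any():
            break
        ma = mk[active][:, None]
        aa = alpha[active][:, None]
        denom = 1.0 + aa * s[None, :] * ma
        f = ((y[active] - s[None, :] * ma) / denom).sum(axis=1)
        fp = -(s[None, :] * (1.0 + aa * y[active]) / denom**2).sum(axis=1)
        new = np.maximum(mk[active] - f / fp, mk[active] * 1e-3)
        conv = np.abs(new - mk[active]) <= 1e-12 + 1e-10 * new
        mk[active] = new
        idx = np.where(active)[0]
        active[idx[conv]] = False
    return mk


def nb_wald_de(counts, size_factors: pd.Series, dispersions: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """Per-gene NB Wald test of the two-group effect.

    Fits the log-link NB model mean = s_j * exp(b0 + b1*x_j) per gene
    with the dispersion fixed at its estimate, computes the Wald
    statistic z = b1_hat / SE(b1_hat) from the observed information,
    two-sided normal p-values and BH-adjusted p-values. Genes with all
    zero counts, or zero counts throughout one group, cannot support a
    finite effect estimate: they get missing statistics and are excluded
    from the BH denominator.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc,
    stat, p, padj, significant. The fold change numerator is the case
    (MSA) group.
    """
    cm = counts if isinstance(counts, CountMatrix) else None
    if cm is None:
        raise TypeError("nb_wald_de expects a CountMatrix")
    x = cm.values.to_numpy(dtype=float)
    s = size_factors.loc[cm.values.columns].to_numpy(dtype=float)
    disp = dispersions.loc[cm.values.index, "alpha"].to_numpy(dtype=float)
    ind = cm.group_indicator()
    cols0, cols1 = ind == 0, ind == 1

    m0 = _nb_group_mean(x[:, cols0], s[cols0], disp)
    m1 = _nb_group_mean(x[:, cols1], s[cols1], disp)

    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = np.log(m1) - np.log(m0)
        # observed information per group at the MLE (log-link NB, fixed alpha)
        info0 = _observed_info(x[:, cols0], s[cols0], m0, disp)
        info1 = _observed_info(x[:, cols1], s[cols1], m1, disp)
        var_b1 = 1.0 / info0 + 1.0 / info1
        z = b1 / np.sqrt(var_b1)

    from scipy import stats as sps

    ok = np.isfinite(z)
    p = np.where(ok, 2.0 * sps.norm.sf(np.abs(np.where(ok, z, 0.0))), np.nan)
    padj = bh_adjust(p)
    base_mean = (x / s).mean(axis=1)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": b1 / LN2,
            "stat": z,
            "p": p,
            "padj": padj,
            "significant": padj < alpha,
        },
        index=cm.values.index,
    )
    out.index.name = "feature_id"
    return out


def _observed_info(y: np.ndarray, s: np.ndarray, m: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Observed information for the group log-mean at the MLE."""
    mu = s[None, :] * m[:, None]
    denom = 1.0 + alpha[:, None] * mu
    info = (mu * (1.0 + alpha[:, None] * y) / denom**2).sum(axis=1)
    return np.where(m > 0, info, np.nan)


class NegativeBinomialWaldDE(BaseEstimator):
    """Two-group negative-binomial Wald differential expression.

    Parameters
    ----------
    alpha : float, default 0.1
        BH-adjusted p-value threshold for the significance call.
    shrink_weight : float, default 0.5
        Weight of the fitted mean-dispersion trend in the final
        dispersion (0 = raw gene-wise estimate, 1 = pure trend).
    drop_all_zero : bool, default True
        Remove genes with zero counts in every sample before testing.

    Attributes
    ----------
    size_factors_ : pd.Series per sample.
    dispersions_ : pd.DataFrame of dispersion estimates per gene.
    results_ : pd.DataFrame with base_mean, log2fc, stat, p, padj,
        significant per tested gene.
    filter_report_ : FilterChain describing genes removed before testing.
    """

    def __init__(self, alpha: float = 0.1, shrink_weight: float = 0.5, drop_all_zero: bool = True):
        self.alpha = alpha
        self.shrink_weight = shrink_weight
        self.drop_all_zero = drop_all_zero

    def fit(self, counts: CountMatrix, y=None):
        cm = counts
        chain = FilterChain()
        n0 = cm.values.shape[0]
        if self.drop_all_zero:
            keep = cm.values.sum(axis=1) > 0
            chain.add("all_zero", n0, int((~keep).sum()), "sum(counts) == 0")
            cm = CountMatrix(cm.values.loc[keep], cm.samples)
        self.size_factors_ = estimate_size_factors(cm)
        self.dispersions_ = estimate_dispersions(cm, self.size_factors_, self.shrink_weight)
        self.results_ = nb_wald_de(cm, self.size_factors_, self.dispersions_, self.alpha)
        self.filter_report_ = chain
        return self

    def significant_features(self) -> pd.Index:
        return self.results_.index[self.results_["significant"].fillna(False)]
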