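"""Two-color dye-swap miRNA array processing and single-channel DE.

Processing chain for the dye-swap design: background-correct each spot
(net = foreground - local background), form M/A values, remove
intensity-dependent bias by print-tip loess within arrays, quantile
normalize A between arrays, filter probes (species annotation, variance
above the shorth), fit the balanced dye-swap linear model per probe, and
moderate the t-statistics by empirical Bayes. Single-channel log2
matrices (mRNA arrays) go through an IQR filter and a two-group
moderated t-test instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .report import FilterChain
from .stats import EBayesParams, bh_adjust, moderated_t

__all__ = [
    "TwoColorArraySet",
    "MAValues",
    "compute_ma",
    "normalize_within",
    "normalize_between",
    "channel_log2_matrix",
    "probe_m_matrix",
    "nonspecific_filter",
    "iqr_filter",
    "shorth",
    "fit_dyeswap",
    "ebayes_moderated_t",
    "single_channel_de",
    "DyeSwapModeratedDE",
    "TwoGroupModeratedT",
    "dyeswap_de_pipeline",
]

ORIENTATIONS = ("MSA_in_red", "MSA_in_green")
SPOT_COLUMNS = ("probe_id", "printtip", "fg_r", "bg_r", "fg_g", "bg_g")


@dataclass
class TwoColorArraySet:
    """Spot tables plus per-array metadata and probe annotation.

    ``arrays`` maps array id to a spot table with columns ``probe_id,
    printtip, fg_r, bg_r, fg_g, bg_g`` (one row per spot; duplicate
    spots of a probe are separate rows). ``meta`` is indexed by array id
    with columns ``orientation`` (``MSA_in_red``/``MSA_in_green``) and
    ``pool``. ``probe_annotation`` is indexed by probe id with a
    ``species`` column.
    """

    arrays: dict[str, pd.DataFrame]
    meta: pd.DataFrame
    probe_annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for aid, tab in self.arrays.items():
            missing = set(SPOT_COLUMNS) - set(tab.columns)
            if missing:
                raise ValueError(f"array {aid} spot table lacks columns {sorted(missing)}")
            inten = tab[["fg_r", "bg_r", "fg_g", "bg_g"]].to_numpy(dtype=float)
            if np.any(inten < 0):
                raise ValueError(f"array {aid} has negative raw intensities")
        unknown = set(self.arrays) - set(self.meta.index)
        if unknown:
            raise ValueError(f"arrays without metadata: {sorted(unknown)}")
        bad = set(self.meta.loc[list(self.arrays), "orientation"]) - set(ORIENTATIONS)
        if bad:
            raise ValueError(f"unknown dye orientations: {sorted(bad)}")

    def orientation_sign(self, array_id: str) -> int:
        """+1 when the MSA sample is in the red channel, else -1."""
        return 1 if self.meta.loc[array_id, "orientation"] == "MSA_in_red" else -1


@dataclass
class MAValues:
    """Per-array spot-level M/A values; NaN marks missing spots."""

    tables: dict[str, pd.DataFrame]  # columns: probe_id, printtip, M, A
    meta: pd.DataFrame
    probe_annotation: pd.DataFrame | None = None
    history: list[str] = field(default_factory=list)

    def copy(self) -> "MAValues":
        return MAValues(
            {k: v.copy() for k, v in self.tables.items()},
            self.meta,
            self.probe_annotation,
            list(self.history),
        )


def compute_ma(arrays: TwoColorArraySet) -> MAValues:
    """Background-corrected M/A values per spot.

    net = fg - bg per channel; M = log2(netR/netG), A = (log2 netR +
    log2 netG)/2. Spots with non-positive net intensity in either
    channel are marked missing (no offset-based rescue).
    """
    tables = {}
    for aid, tab in arrays.arrays.items():
        net_r = tab["fg_r"].to_numpy(dtype=float) - tab["bg_r"].to_numpy(dtype=float)
        net_g = tab["fg_g"].to_numpy(dtype=float) - tab["bg_g"].to_numpy(dtype=float)
        ok = (net_r > 0) & (net_g > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.where(ok, np.log2(np.where(ok, net_r, 1.0)), np.nan)
            lg = np.where(ok, np.log2(np.where(ok, net_g, 1.0)), np.nan)
            # M via the ratio keeps exact dyadic cases (e.g. 320/160) exact
            m = np.where(ok, np.log2(np.where(ok, net_r, 1.0) / np.where(ok, net_g, 1.0)), np.nan)
        tables[aid] = pd.DataFrame(
            {
                "probe_id": tab["probe_id"].to_numpy(),
                "printtip": tab["printtip"].to_numpy(),
                "M": m,
                "A": (lr + lg) / 2.0,
            },
            index=tab.index,
        )
    return MAValues(tables, arrays.meta, arrays.probe_annotation, ["compute_ma"])


def normalize_within(
    ma: MAValues, span: float = 0.4, iterations: int = 4, min_spots: int = 20
) -> MAValues:
    """Print-tip loess normalization of M on A within each array.

    Per print-tip group a robust local linear fit (degree 1, ``span``,
    ``iterations`` robustifying iterations) of M on A is subtracted.
    Groups with fewer than ``min_spots`` non-missing spots fall back to
    the array-wide fit; all-missing groups are left unchanged with a
    warning.
    """
    out = ma.copy()
    for aid, tab in out.tables.items():
        m = tab["M"].to_numpy(dtype=float)
        a = tab["A"].to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(a)
        if ok.sum() >= 2:
            array_fit = np.full(m.size, np.nan)
            array_fit[ok] = lowess(
                m[ok], a[ok], frac=span, it=iterations, return_sorted=False
            )
        else:
            array_fit = np.zeros(m.size)
        corrected = m.copy()
        for tip, idx in tab.groupby("printtip").groups.items():
            loc = tab.index.get_indexer(idx)
            sel = ok[loc]
            if sel.sum() == 0:
                warnings.warn(f"array {aid} print-tip {tip}: all spots missing; left unchanged")
                continue
            if sel.sum() >= min_spots:
                fit = lowess(
                    m[loc][sel], a[loc][sel], frac=span, it=iterations, return_sorted=False
                )
                corrected[loc[sel]] = m[loc][sel] - fit
            else:
                corrected[loc[sel]] = m[loc][sel] - array_fit[loc[sel]]
        tab["M"] = corrected
    out.history.append("normalize_within")
    return out


def _quantile_reference(columns: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean order-statistic curve over arrays, on a common quantile grid."""
    n_max = max(c.size for c in columns)
    grid = np.linspace(0.0, 1.0, n_max)
    interp = []
    for c in columns:
        srt = np.sort(c)
        if srt.size == 1:
            interp.append(np.full(n_max, srt[0]))
        else:
            q = np.linspace(0.0, 1.0, srt.size)
            interp.append(np.interp(grid, q, srt))
    return grid, np.mean(interp, axis=0)


def normalize_between(ma: MAValues) -> MAValues:
    """Quantile normalization of A-values between arrays; M untouched.

    Each array's sorted A-values are replaced by the cross-array mean of
    the order statistics; tied values receive the mean of the order
    statistics they span (average ranks). Arrays with differing numbers
    of usable spots are aligned through quantile interpolation.
    """
    out = ma.copy()
    cols = {}
    for aid, tab in out.tables.items():
        a = tab["A"].to_numpy(dtype=float)
        cols[aid] = a[np.isfinite(a)]
    if not cols or min(c.size for c in cols.values()) == 0:
        raise ValueError("quantile normalization needs non-missing A values in every array")
    grid, ref = _quantile_reference(list(cols.values()))
    for aid, tab in out.tables.items():
        a = tab["A"].to_numpy(dtype=float)
        ok = np.isfinite(a)
        n = ok.sum()
        ranks = sps.rankdata(a[ok], method="average")  # ties -> mean of spanned positions
        q = (ranks - 1.0) / (n - 1.0) if n > 1 else np.full(ranks.shape, 0.5)
        new = np.interp(q, grid, ref)
        a2 = a.copy()
        a2[ok] = new
        tab["A"] = a2
    out.history.append("normalize_between")
    return out


def channel_log2_matrix(arrays: TwoColorArraySet) -> pd.DataFrame:
    """Per-sample log2 net-intensity expression matrix from the channels.

    Each array measures two samples (one per channel); log2 net
    intensities are averaged over duplicate spots and over the arrays
    carrying the same sample. Used for the matched-sample correlation
    step, which needs per-sample miRNA expression rather than ratios.
    """
    frames = []
    for aid, tab in arrays.arrays.items():
        sign = arrays.orientation_sign(aid)
        pool = arrays.meta.loc[aid, "pool"]
        red_sample = f"MSA_{pool}" if sign == 1 else f"CTL_{pool}"
        green_sample = f"CTL_{pool}" if sign == 1 else f"MSA_{pool}"
        net_r = tab["fg_r"].to_numpy(float) - tab["bg_r"].to_numpy(float)
        net_g = tab["fg_g"].to_numpy(float) - tab["bg_g"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            lr = np.where(net_r > 0, np.log2(np.where(net_r > 0, net_r, 1.0)), np.nan)
            lg = np.where(net_g > 0, np.log2(np.where(net_g > 0, net_g, 1.0)), np.nan)
        frames.append(pd.DataFrame({"probe_id": tab["probe_id"], "sample": red_sample, "value": lr}))
        frames.append(pd.DataFrame({"probe_id": tab["probe_id"], "sample": green_sample, "value": lg}))
    long = pd.concat(frames, ignore_index=True)
    return long.pivot_table(index="probe_id", columns="sample", values="value", aggfunc="mean")


def probe_m_matrix(ma: MAValues) -> pd.DataFrame:
    """Probe x array M matrix with duplicate spots averaged within array."""
    cols = {}
    for aid, tab in ma.tables.items():
        cols[aid] = tab.groupby("probe_id")["M"].mean()
    mat = pd.DataFrame(cols)
    mat.index.name = "probe_id"
    return mat


def shorth(x) -> float:
    """Mean of the shortest interval containing ceil(n/2) of the values."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("shorth of an empty vector")
    h = int(np.ceil(n / 2))
    widths = x[h - 1 :] - x[: n - h + 1]
    i = int(np.argmin(widths))
    return float(x[i : i + h].mean())


def nonspecific_filter(
    matrix: pd.DataFrame, annotation: pd.DataFrame | None = None, species: str = "mouse"
) -> tuple[pd.DataFrame, FilterChain]:
    """Annotation and variance filter on a probe x array matrix.

    Probes lacking a ``species`` annotation are removed first; then
    per-probe SDs across arrays are computed and only probes with
    SD strictly greater than the shorth of the SD distribution are kept.
    If the variance rule would remove every probe (degenerate SD
    distribution) all probes are kept with a warning.
    """
    if matrix.shape[1] < 3:
        raise ValueError("nonspecific filtering needs at least 3 arrays")
    chain = FilterChain()
    n0 = matrix.shape[0]
    if annotation is not None:
        annotated = annotation.index[annotation["species"] == species]
        keep = matrix.index.isin(annotated)
        chain.add("annotation", n0, int((~keep).sum()), f"species == {species!r}")
        matrix = matrix.loc[keep]
    sd = matrix.std(axis=1, ddof=1)
    cut = shorth(sd.to_numpy())
    keep = sd > cut
    if keep.sum() == 0:
        warnings.warn("variance filter would remove all probes; keeping all (degenerate case)")
        chain.add("variance", matrix.shape[0], 0, f"SD > shorth = {cut:.4g} (degenerate: kept all)")
        return matrix, chain
    chain.add("variance", matrix.shape[0], int((~keep).sum()), f"SD > shorth = {cut:.4g}")
    return matrix.loc[keep], chain


def iqr_filter(log2matrix: pd.DataFrame, threshold: float = 0.35) -> tuple[pd.DataFrame, FilterChain]:
    """Keep rows whose interquartile range exceeds ``threshold``.

    Quartiles use linear interpolation; the comparison is strict.
    """
    q1 = log2matrix.quantile(0.25, axis=1)
    q3 = log2matrix.quantile(0.75, axis=1)
    keep = (q3 - q1) > threshold
    chain = FilterChain()
    chain.add("iqr", log2matrix.shape[0], int((~keep).sum()), f"IQR > {threshold}")
    return log2matrix.loc[keep], chain


def fit_dyeswap(m_matrix: pd.DataFrame, orientations: pd.Series) -> pd.DataFrame:
    """Balanced dye-swap linear model per probe.

    For each probe, least-squares fit of the (duplicate-averaged) M
    values on the orientation design x_a in {+1 (MSA in red), -1 (MSA in
    green)} with no intercept. The coefficient is the MSA - control
    log2 fold change; a constant dye bias cancels in a balanced design.
    Probes observed on fewer than 2 arrays are excluded.

    Returns a DataFrame with columns coef, s2 (residual variance), df,
    n_arrays and stdev_unscaled.
    """
    x = orientations.loc[m_matrix.columns].to_numpy(dtype=float)
    if not (np.any(x > 0) and np.any(x < 0)):
        raise ValueError("dye-swap fit needs arrays of both orientations")
    M = m_matrix.to_numpy(dtype=float)
    obs = np.isfinite(M)
    n = obs.sum(axis=1)
    xm = np.where(obs, x[None, :] * M, 0.0)
    xx = np.where(obs, x[None, :] ** 2, 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = xm.sum(axis=1) / xx
        resid = np.where(obs, M - coef[:, None] * x[None, :], 0.0)
        df = n - 1
        s2 = (resid**2).sum(axis=1) / np.where(df > 0, df, np.nan)
        u = 1.0 / np.sqrt(xx)
    out = pd.DataFrame(
        {"coef": coef, "s2": s2, "df": df.astype(float), "n_arrays": n, "stdev_unscaled": u},
        index=m_matrix.index,
    )
    kept = out[out["n_arrays"] >= 2].copy()
    dropped = out.shape[0] - kept.shape[0]
    if dropped:
        warnings.warn(f"{dropped} probes observed on fewer than 2 arrays were excluded from the fit")
    return kept


def ebayes_moderated_t(
    fits: pd.DataFrame, alpha: float = 0.1, params: EBayesParams | None = None
) -> pd.DataFrame:
    """Moderated t-test on per-probe linear-model fits.

    ``fits`` needs columns coef, s2, df, stdev_unscaled (as produced by
    :func:`fit_dyeswap` or :func:`single_channel_de`'s internal fit).
    Hyperparameters are estimated by the scaled-F moment match unless
    ``params`` overrides them (d0 = 0 gives the ordinary t, d0 = inf the
    fully pooled statistic). Significance: BH-adjusted p < ``alpha``.
    """
    if params is None and (fits["df"] > 0).sum() < 10:
        raise ValueError("hyperparameter estimation needs at least 10 probes with positive df")
    t, p, df_total, params = moderated_t(
        fits["coef"].to_numpy(),
        fits["stdev_unscaled"].to_numpy(),
        fits["s2"].to_numpy(),
        fits["df"].to_numpy(),
        params,
    )
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2fc": fits["coef"].to_numpy(),
            "t": t,
            "df_total": df_total,
            "p": p,
            "padj": padj,
            "significant": padj < alpha,
        },
        index=fits.index,
    )
    out.attrs["ebayes_params"] = params
    out.index.name = "feature_id"
    return out


def _two_group_fits(log2matrix: pd.DataFrame, groups: pd.Series, case: str = "MSA") -> pd.DataFrame:
    g = groups.loc[log2matrix.columns]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    case_label = case if case in labels else labels[-1]
    is_case = (g == case_label).to_numpy()
    n1, n0 = int(is_case.sum()), int((~is_case).sum())
    if min(n0, n1) < 2:
        raise ValueError("both groups need at least two samples")
    X = log2matrix.to_numpy(dtype=float)
    m1 = X[:, is_case].mean(axis=1)
    m0 = X[:, ~is_case].mean(axis=1)
    ss = X[:, is_case].var(axis=1, ddof=1) * (n1 - 1) + X[:, ~is_case].var(axis=1, ddof=1) * (n0 - 1)
    df = n0 + n1 - 2
    return pd.DataFrame(
        {
            "coef": m1 - m0,
            "s2": ss / df,
            "df": float(df),
            "stdev_unscaled": np.sqrt(1.0 / n0 + 1.0 / n1),
        },
        index=log2matrix.index,
    )


def single_channel_de(
    log2matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.1,
    params: EBayesParams | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test on a single-channel log2 matrix."""
    fits = _two_group_fits(log2matrix, groups)
    return ebayes_moderated_t(fits, alpha=alpha, params=params)


class DyeSwapModeratedDE(BaseEstimator):
    """Dye-swap two-color array differential expression.

    Runs the full chain: M/A computation, print-tip loess, between-array
    quantile normalization (A values), duplicate averaging, nonspecific
    filtering (species annotation + shorth variance rule), dye-swap
    linear model and empirical-Bayes moderated t.

    Attributes (after fit): ``ma_``, ``m_matrix_``, ``fits_``,
    ``results_``, ``filter_report_``, ``ebayes_params_``.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        span: float = 0.4,
        iterations: int = 4,
        min_spots: int = 20,
        species: str = "mouse",
        apply_filters: bool = True,
        d0_override: float | None = None,
    ):
        self.alpha = alpha
        self.span = span
        self.iterations = iterations
        self.min_spots = min_spots
        self.species = species
        self.apply_filters = apply_filters
        self.d0_override = d0_override

    def fit(self, arrays: TwoColorArraySet, y=None):
        ma = compute_ma(arrays)
        ma = normalize_within(ma, self.span, self.iterations, self.min_spots)
        ma = normalize_between(ma)
        self.ma_ = ma
        mat = probe_m_matrix(ma)
        if self.apply_filters:
            mat, chain = nonspecific_filter(mat, arrays.probe_annotation, self.species)
        else:
            chain = FilterChain()
        self.m_matrix_ = mat
        self.filter_report_ = chain
        orientations = pd.Series(
            {aid: arrays.orientation_sign(aid) for aid in mat.columns}, name="orientation"
        )
        self.fits_ = fit_dyeswap(mat, orientations)
        params = None
        if self.d0_override is not None:
            from .stats import fit_scaled_f

            base = fit_scaled_f(self.fits_["s2"], self.fits_["df"])
            params = EBayesParams(self.d0_override, base.s0_sq)
        self.results_ = ebayes_moderated_t(self.fits_, self.alpha, params)
        self.ebayes_params_ = self.results_.attrs["ebayes_params"]
        return self

    def significant_features(self) -> pd.Index:
        return self.results_.index[self.results_["significant"].fillna(False)]


class TwoGroupModeratedT(BaseEstimator):
    """Moderated t-test DE on a single-channel log2 expression matrix.

    Applies the IQR filter (default threshold 0.35) and the two-group
    empirical-Bayes moderated t-test; significance at BH-adjusted
    p < ``alpha``.
    """

    def __init__(self, alpha: float = 0.1, iqr_threshold: float = 0.35, apply_iqr: bool = True,
                 d0_override: float | None = None):
        self.alpha = alpha
        self.iqr_threshold = iqr_threshold
        self.apply_iqr = apply_iqr
        self.d0_override = d0_override

    def fit(self, log2matrix: pd.DataFrame, groups: pd.Series):
        mat = log2matrix
        if self.apply_iqr:
            mat, chain = iqr_filter(mat, self.iqr_threshold)
        else:
            chain = FilterChain()
        self.filter_report_ = chain
        fits = _two_group_fits(mat, groups)
        params = None
        if self.d0_override is not None:
            from .stats import fit_scaled_f

            base = fit_scaled_f(fits["s2"], fits["df"])
            params = EBayesParams(self.d0_override, base.s0_sq)
        self.fits_ = fits
        self.results_ = ebayes_moderated_t(fits, self.alpha, params)
        self.ebayes_params_ = self.results_.attrs["ebayes_params"]
        return self

    def significant_features(self) -> pd.Index:
        return self.results_.index[self.results_["significant"].fillna(False)]


def dyeswap_de_pipeline(arrays: TwoColorArraySet, alpha: float = 0.1, **kwargs) -> pd.DataFrame:
    """Convenience wrapper: full dye-swap DE chain, returns the result table."""
    return DyeSwapModeratedDE(alpha=alpha, **kwargs).fit(arrays).results_
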