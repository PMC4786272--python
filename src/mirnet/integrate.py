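"""Cross-platform combination, correlation, evidence filtering, network.

This is the integration stage: combine the significant features from the
count-based and array-based analyses, compute matched-sample Pearson
correlations between differentially expressed miRNAs and mRNAs, apply
the three-clause target-evidence filter with the negative-correlation
floor, and assemble the resulting interactions into a bipartite
regulatory network for export.

The evidence filter keeps a (miRNA, mRNA) pair when at least one of
three clauses holds — (i) a target-prediction p-value below the cutoff,
(ii) prediction by at least two programs, (iii) an experimentally
validated interaction — and, in all cases, the Pearson correlation is at
or below the floor (default -0.3, i.e. a negative correlation of
magnitude at least 0.3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "combine_platform_de",
    "RegionOverlap",
    "cross_region_overlap",
    "correlate_pairs",
    "filter_interactions",
    "build_network",
    "write_sif",
]

PROGRAM_COLS = ("pred_mirwalk", "pred_rna22", "pred_miranda", "pred_targetscan")
ANNOTATION_COLS = ("mirna_id", "gene_id", "mirwalk_p", *PROGRAM_COLS, "validated")


def combine_platform_de(rnaseq: pd.DataFrame, array: pd.DataFrame) -> pd.DataFrame:
    """Union of per-platform significant features with mean fold change.

    Both inputs are DE tables indexed by feature id with ``log2fc``,
    ``padj`` and ``significant`` columns. The output holds one row per
    feature significant on at least one platform, the per-platform stats,
    the mean of the available log2 fold changes (for display), a
    ``source`` column in {rnaseq, array, both} (both = significant on
    both platforms), and a ``direction_conflict`` flag where the
    available platform fold changes disagree in sign — conflicts are
    flagged, never silently averaged away.
    """
    if len(rnaseq) and len(array) and not (set(rnaseq.index) & set(array.index)):
        raise ValueError(
            "no feature identifier is shared between the platform tables; "
            "identifier namespaces look inconsistent"
        )
    sig_r = set(rnaseq.index[rnaseq["significant"].fillna(False)])
    sig_a = set(array.index[array["significant"].fillna(False)])
    features = sorted(sig_r | sig_a)
    rows = []
    for f in features:
        lr = rnaseq["log2fc"].get(f, np.nan)
        la = array["log2fc"].get(f, np.nan)
        avail = [v for v in (lr, la) if np.isfinite(v)]
        source = "both" if (f in sig_r and f in sig_a) else ("rnaseq" if f in sig_r else "array")
        rows.append(
            {
                "feature_id": f,
                "rnaseq_log2fc": lr,
                "rnaseq_padj": rnaseq["padj"].get(f, np.nan),
                "array_log2fc": la,
                "array_padj": array["padj"].get(f, np.nan),
                "mean_log2fc": float(np.mean(avail)) if avail else np.nan,
                "source": source,
                "direction_conflict": len(avail) == 2 and np.sign(lr) != np.sign(la),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("feature_id")
    return out


@dataclass
class RegionOverlap:
    """Set partition of two signed DE lists from different regions."""

    common: set
    only_a: set
    only_b: set
    opposite_direction: set

    def __post_init__(self) -> None:
        assert self.opposite_direction <= self.common


def cross_region_overlap(list_a: pd.Series, list_b: pd.Series) -> RegionOverlap:
    """Exact overlap partition of two feature->log2fc mappings.

    ``opposite_direction`` collects the common features whose fold
    changes disagree in sign between the regions.
    """
    a, b = dict(list_a), dict(list_b)
    common = set(a) & set(b)
    opposite = {f for f in common if np.sign(a[f]) != np.sign(b[f])}
    return RegionOverlap(common, set(a) - common, set(b) - common, opposite)


def correlate_pairs(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    sample_map: pd.DataFrame,
    min_matched: int = 3,
    allow_low_n: bool = False,
) -> pd.DataFrame:
    """Pearson correlation for every (miRNA, mRNA) feature pair.

    ``sample_map`` pairs the columns of the two matrices (columns
    ``mirna_sample`` and ``mrna_sample``, one row per matched sample,
    normally keyed by pool id); columns absent from either matrix are
    dropped with a warning. Pairs with a zero-variance vector get a
    missing correlation. Fewer than ``min_matched`` matched samples is
    an error unless ``allow_low_n`` is set.
    """
    ok = sample_map["mirna_sample"].isin(mirna_expr.columns) & sample_map["mrna_sample"].isin(
        mrna_expr.columns
    )
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} sample pairs dropped: columns missing from a matrix")
    pairs = sample_map[ok]
    n = len(pairs)
    if n < min_matched:
        msg = f"only {n} matched samples (min_matched = {min_matched})"
        if not allow_low_n:
            raise ValueError(msg + "; pass allow_low_n=True to proceed")
        warnings.warn(msg + "; proceeding (allow_low_n)")
    X = mirna_expr[pairs["mirna_sample"]].to_numpy(dtype=float)
    Y = mrna_expr[pairs["mrna_sample"]].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc @ Yc.T) / np.outer(xs, ys)
    R[:, ys == 0] = np.nan
    R[xs == 0, :] = np.nan
    mi, gi = np.meshgrid(np.arange(len(mirna_expr)), np.arange(len(mrna_expr)), indexing="ij")
    out = pd.DataFrame(
        {
            "mirna_id": mirna_expr.index.to_numpy()[mi.ravel()],
            "gene_id": mrna_expr.index.to_numpy()[gi.ravel()],
            "r": R.ravel(),
            "n_matched": n,
        }
    )
    return out


def filter_interactions(
    candidates: pd.DataFrame,
    annotations: pd.DataFrame,
    enriched_genes=None,
    r_floor: float = -0.3,
    p_cut: float = 0.1,
    mirwalk_in_programs: bool = True,
) -> pd.DataFrame:
    """Three-clause evidence filter with the negative-correlation floor.

    A candidate is kept iff at least one evidence clause holds
    (``mirwalk_p < p_cut``; predicted by >= 2 programs; validated), its
    correlation satisfies ``r <= r_floor`` (missing r never passes), and
    — when ``enriched_genes`` is supplied — its gene belongs to that
    set. ``mirwalk_in_programs`` controls whether the mirWalk prediction
    flag counts toward the two-program clause. Absent annotation rows
    mean no evidence. The returned table adds the evidence columns,
    ``clauses_met`` and ``kept``.
    """
    if r_floor > 0:
        raise ValueError("r_floor must be <= 0: the filter is defined for negative correlation")
    ann = annotations.copy()
    missing = set(ANNOTATION_COLS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    if ann.duplicated(subset=["mirna_id", "gene_id"]).any():
        raise ValueError("annotation table has duplicate (miRNA, gene) rows")
    out = candidates.merge(ann[list(ANNOTATION_COLS)], on=["mirna_id", "gene_id"], how="left")
    for c in PROGRAM_COLS + ("validated",):
        out[c] = np.where(out[c].isna(), False, out[c]).astype(bool)
    prog_cols = list(PROGRAM_COLS) if mirwalk_in_programs else [c for c in PROGRAM_COLS if c != "pred_mirwalk"]
    n_programs = out[list(PROGRAM_COLS)].sum(axis=1)
    clause_p = out["mirwalk_p"].to_numpy(dtype=float) < p_cut
    clause_prog = out[prog_cols].sum(axis=1).to_numpy() >= 2
    clause_val = out["validated"].to_numpy()
    r = out["r"].to_numpy(dtype=float)
    corr_ok = np.isfinite(r) & (r <= r_floor)
    evidence = clause_p | clause_prog | clause_val
    kept = evidence & corr_ok
    if enriched_genes is not None:
        kept = kept & out["gene_id"].isin(set(enriched_genes)).to_numpy()
    clause_names = np.array(["mirwalk_p", "two_programs", "validated"])
    out["clauses_met"] = [
        ",".join(clause_names[[a, b, c]]) for a, b, c in zip(clause_p, clause_prog, clause_val)
    ]
    out["n_programs"] = n_programs
    out["kept"] = kept
    return out


def build_network(kept: pd.DataFrame, de_info: pd.Series | dict | None = None) -> nx.DiGraph:
    """Bipartite miRNA -> mRNA regulatory network from kept interactions.

    Node attributes: ``kind`` (miRNA/mRNA), ``log2fc`` (mean fold change
    from ``de_info`` when available) and ``degree``; edge attributes:
    ``r`` and ``n_programs``. An empty input yields an empty graph.
    """
    lfc = dict(de_info) if de_info is not None else {}
    g = nx.DiGraph()
    for row in kept.itertuples(index=False):
        g.add_node(row.mirna_id, kind="miRNA", log2fc=float(lfc.get(row.mirna_id, np.nan)))
        g.add_node(row.gene_id, kind="mRNA", log2fc=float(lfc.get(row.gene_id, np.nan)))
        g.add_edge(
            row.mirna_id,
            row.gene_id,
            r=float(row.r),
            n_programs=int(getattr(row, "n_programs", 0)),
        )
    deg = dict(g.degree())
    nx.set_node_attributes(g, deg, "degree")
    return g


def write_sif(graph: nx.DiGraph, path, relation: str = "represses") -> None:
    """Simple-interaction-format export (source relation target per line)."""
    lines = [f"{u}\t{relation}\t{v}" for u, v in graph.edges()]
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
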