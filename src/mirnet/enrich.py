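"""Direction-separated gene-set enrichment and miRNA family enrichment.

Category enrichment is the classical one-sided hypergeometric
(over-representation) test, run separately for up- and down-regulated
gene lists against an explicit background, with the rule that a term
must contain at least two differentially expressed genes to be called
significant (raw p < 0.05 by default). Family enrichment tests whether
the fold changes of a miRNA family's members are shifted relative to all
other scored miRNAs (two-sample t, one-sided per direction).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "read_gmt",
    "write_gmt",
    "hypergeometric_term_test",
    "enrich_categories",
    "mirna_family_enrich",
]


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict[str, set], path, descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for name, members in sets.items():
        desc = (descriptions or {}).get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_term_test(de, background, term):
    """Exact hypergeometric tail P(X >= k) for one term.

    The DE list must be a subset of the background; the term is
    intersected with the background before counting. Returns
    (k, K, n, N, p).
    """
    background = set(background)
    if not background:
        raise ValueError("background is empty")
    de = set(de)
    if not de <= background:
        raise ValueError("DE list must be a subset of the background")
    term = set(term) & background
    N, K, n = len(background), len(term), len(de)
    k = len(de & term)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, p


def enrich_categories(
    de_up,
    de_down,
    background,
    collection: dict[str, set],
    p_cut: float = 0.05,
    min_genes: int = 2,
    adjust: bool = False,
    q_cut: float | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment per term, separately per direction.

    A term is significant when p < ``p_cut`` and it contains at least
    ``min_genes`` DE genes of that direction. With ``adjust=True`` a BH
    q-value column is added and ``q_cut`` (when given) replaces the raw
    p cutoff in the significance call. Terms with no background overlap
    are skipped. Results are sorted by p within direction.
    """
    de_up, de_down = set(de_up), set(de_down)
    if de_up & de_down:
        raise ValueError("up- and down-regulated lists must be disjoint")
    rows = []
    skipped = []
    for direction, de in (("up", de_up), ("down", de_down)):
        for term_id, members in collection.items():
            if not set(members) & set(background):
                skipped.append(term_id)
                continue
            k, K, n, N, p = hypergeometric_term_test(de, background, members)
            rows.append(
                {
                    "term": term_id,
                    "direction": direction,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                    "passes_min_gene": k >= min_genes,
                }
            )
    if skipped:
        warnings.warn(f"{len(set(skipped))} terms had no background overlap and were skipped")
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if adjust:
        out["q"] = np.nan
        for direction in ("up", "down"):
            sel = out["direction"] == direction
            from .stats import bh_adjust

            out.loc[sel, "q"] = bh_adjust(out.loc[sel, "p"].to_numpy())
        cut_ok = out["q"] < q_cut if q_cut is not None else out["p"] < p_cut
    else:
        cut_ok = out["p"] < p_cut
    out["significant"] = cut_ok & out["passes_min_gene"]
    out = out.sort_values(["direction", "p"], kind="mergesort").reset_index(drop=True)
    return out


def mirna_family_enrich(log2fc: pd.Series, family_map: dict[str, set]) -> pd.DataFrame:
    """Family-level shift test on per-miRNA log2 fold changes.

    Per family, a two-sample (Welch) t of the member fold changes versus
    all non-member fold changes; one-sided p-values for up- and
    down-shift are computed and the smaller is reported with its
    direction. Families with fewer than 2 scored members, or with an
    empty complement, are skipped with a warning.
    """
    log2fc = log2fc.dropna()
    rows = []
    for fam, members in family_map.items():
        vals = log2fc.loc[log2fc.index.intersection(members)]
        rest = log2fc.loc[~log2fc.index.isin(members)]
        if len(vals) < 2 or len(rest) < 2:
            warnings.warn(f"family {fam}: fewer than 2 scored members or empty complement; skipped")
            continue
        t = sps.ttest_ind(vals, rest, equal_var=False)
        p_up = sps.ttest_ind(vals, rest, equal_var=False, alternative="greater").pvalue
        p_down = sps.ttest_ind(vals, rest, equal_var=False, alternative="less").pvalue
        direction = "up" if p_up <= p_down else "down"
        rows.append(
            {
                "family": fam,
                "n_members": len(vals),
                "mean_log2fc": float(vals.mean()),
                "t": float(t.statistic),
                "p_up": float(p_up),
                "p_down": float(p_down),
                "p": float(min(p_up, p_down)),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)
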