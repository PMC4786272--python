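"""Two-sample t-tests from group summary statistics.

Motor-behavior style comparisons where only (n, mean, SEM) per group are
available. The default is the pooled-variance Student t with the
statistic reported as an absolute value and a two-sided p-value; a Welch
variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "pooled_t_from_summary", "summary_table_t", "summarize_samples"]


@dataclass
class GroupSummary:
    """Sample size, mean and standard error of the mean for one group."""

    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)


def summarize_samples(x) -> GroupSummary:
    """(n, mean, sem) summary of a raw sample vector."""
    x = np.asarray(x, dtype=float)
    return GroupSummary(n=x.size, mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(x.size)))


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary, welch: bool = False):
    """|t|, degrees of freedom and two-sided p from group summaries.

    Pooled (Student) variant: s2p = ((na-1)*SDa^2 + (nb-1)*SDb^2) /
    (na+nb-2), t = |mean_a - mean_b| / (sp*sqrt(1/na + 1/nb)), df =
    na+nb-2. Welch variant uses unpooled variances with
    Welch-Satterthwaite df. Two groups with zero variance and equal
    means give t = 0, p = 1; zero variance with unequal means is
    rejected.
    """
    diff = abs(a.mean - b.mean)
    if a.sd == 0 and b.sd == 0:
        if diff == 0:
            return 0.0, a.n + b.n - 2, 1.0
        raise ValueError("both variances are zero with unequal means; t is undefined")
    if welch:
        va, vb = a.sem**2, b.sem**2
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        s2p = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        se = np.sqrt(s2p * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
    t = diff / se
    p = 2.0 * sps.t.sf(t, df)
    return float(t), float(df), float(p)


def summary_table_t(table: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Batch t-tests on a summary table.

    Expects columns ``measure, n_a, mean_a, sem_a, n_b, mean_b, sem_b``;
    returns the table with ``t, df, p`` appended.
    """
    rows = []
    for row in table.itertuples(index=False):
        a = GroupSummary(int(row.n_a), float(row.mean_a), float(row.sem_a))
        b = GroupSummary(int(row.n_b), float(row.mean_b), float(row.sem_b))
        t, df, p = pooled_t_from_summary(a, b, welch=welch)
        rows.append({"measure": row.measure, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)
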