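"""Cohort-level group comparisons: 2x2 chi-square and Welch's t from summaries.

Binary clinical traits (e.g. hypertension, hyperlipidemia) are compared
between groups with the Pearson chi-square test on the 2x2 table, without
Yates continuity correction:

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),  df = 1.

Continuous traits reported as n, mean, sd per group are compared with
Welch's unequal-variance t-test with Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TwoByTwo", "GroupSummary", "chi_square_2x2", "welch_t_test", "compare_traits"]


@dataclass(frozen=True)
class TwoByTwo:
    """Counts with rows = group and columns = trait yes/no: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class GroupSummary:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("standard deviations must be positive")


def chi_square_2x2(table: TwoByTwo) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) and its 1-df p-value."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("degenerate table: zero marginal")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def welch_t_test(summary: GroupSummary) -> tuple[float, float, float]:
    """Welch's t, Satterthwaite df, and the two-sided p, from summary stats."""
    v1 = summary.sd1**2 / summary.n1
    v2 = summary.sd2**2 / summary.n2
    t = (summary.mean1 - summary.mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (summary.n1 - 1) + v2**2 / (summary.n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_traits(df: pd.DataFrame) -> pd.DataFrame:
    """Build a demographics-table-style comparison from a trait table.

    Each row is one trait. Binary traits give columns ``a,b,c,d`` (group 1
    yes/no, group 2 yes/no); continuous traits give
    ``n1,mean1,sd1,n2,mean2,sd2``. A ``trait`` column labels the row.
    Returns a frame with the test used, the statistic, and the p-value.
    """
    out = []
    for _, row in df.iterrows():
        if not pd.isna(row.get("a")):
            stat, p = chi_square_2x2(
                TwoByTwo(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
            )
            out.append({"trait": row["trait"], "test": "chi_square", "statistic": stat, "p_value": p})
        else:
            t, _, p = welch_t_test(
                GroupSummary(
                    n1=int(row["n1"]), n2=int(row["n2"]),
                    mean1=float(row["mean1"]), mean2=float(row["mean2"]),
                    sd1=float(row["sd1"]), sd2=float(row["sd2"]),
                )
            )
            out.append({"trait": row["trait"], "test": "welch_t", "statistic": t, "p_value": p})
    return pd.DataFrame(out, columns=["trait", "test", "statistic", "p_value"])
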