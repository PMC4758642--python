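"""Summary statistics and hypothesis tests for figure-legend style
comparisons: mean ± SEM, 2x2 chi-square, two-sample t-tests, and one-way
ANOVA with Bonferroni-corrected pairwise comparisons.

All tests are two-sided.  Dunnett-style comparisons against a reference
group are approximated by Bonferroni-adjusted pairwise t-tests, which is
conservative (adjusted p-values are never smaller than Dunnett's).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSamples",
    "mean_sem",
    "chi_square_2x2",
    "two_sample_t",
    "anova_bonferroni",
]


@dataclass
class GroupSamples:
    """Named measurement groups (e.g. puncta density per genotype)."""

    groups: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}

    def require_min_n(self, n: int) -> None:
        for name, vals in self.groups.items():
            if len(vals) < n:
                raise ValueError(f"group {name!r} has n={len(vals)} < {n}")


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error (sd with n-1 denominator / sqrt n)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need n >= 2 for a SEM, got n={v.size}")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    (a, b), (c, d) = t
    n = t.sum()
    if n <= 0:
        raise ValueError("table total must be positive")
    marginals = np.array([a + b, c + d, a + c, b + d])
    if np.any(marginals == 0):
        raise ValueError("degenerate table: a row or column marginal is zero")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(marginals)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; Student (pooled) by default.

    Returns (t, df, p).  With zero pooled variance, equal means give
    t = 0 / p = 1 and unequal means give an infinite t with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not welch and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.copysign(np.inf, a.mean() - b.mean())), df, 0.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_bonferroni(
    samples: GroupSamples,
    reference: Optional[str] = None,
    welch: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t-tests.

    With ``reference`` set, comparisons are each group vs the reference
    (a conservative stand-in for Dunnett's test); otherwise all pairs.
    Adjusted p = raw p x number of comparisons, capped at 1.
    Returns (F, p, pairwise table).
    """
    samples.require_min_n(2)
    names = list(samples.groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    if reference is not None and reference not in samples.groups:
        raise KeyError(f"reference group {reference!r} not found")

    arrays = [samples.groups[n] for n in names]
    if np.ptp(np.concatenate(arrays)) == 0:
        F, p = 0.0, 1.0  # all observations identical: no variance to partition
    else:
        with np.errstate(invalid="ignore"):
            F, p = sps.f_oneway(*arrays)
        F, p = float(F), float(p)

    if reference is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    else:
        pairs = [(reference, n) for n in names if n != reference]
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        t, df, praw = two_sample_t(samples.groups[g1], samples.groups[g2],
                                   welch=welch)
        rows.append({
            "group1": g1, "group2": g2, "t": t, "df": df,
            "p_raw": praw, "p_bonferroni": min(1.0, praw * m),
        })
    return F, p, pd.DataFrame(rows)
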