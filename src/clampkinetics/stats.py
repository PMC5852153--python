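"""Cohort statistics: Wilcoxon rank-sum group comparisons with
Benjamini-Hochberg FDR control, and parameter-index correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when n_x + n_y <= 12 and there are no
    ties, the tie-corrected normal approximation otherwise. Returns
    (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1),
    in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation with a p value for the no-correlation hypothesis
    (t-transform with n-2 df). ``method='spearman'`` switches to rank
    correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance sample")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_a: str
    group_b: str
    median_a: float
    q1_a: float
    q3_a: float
    median_b: float
    q1_b: float
    q3_b: float
    statistic: float
    p_raw: float
    p_fdr: float = np.nan

    @property
    def significant(self) -> bool:
        return bool(self.p_fdr < 0.05)


def compare_groups(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    min_group_size: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise two-sided rank-sum tests per variable, BH-corrected across
    the full battery; groups smaller than ``min_group_size`` are dropped with a
    warning column-free (excluded silently from pairs)."""
    groups = [g for g, sub in table.groupby(group_col) if len(sub) >= min_group_size]
    if len(groups) < 2:
        raise ValueError("need at least two groups of sufficient size")
    comps: list[GroupComparison] = []
    for var in variables:
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                a = table.loc[table[group_col] == ga, var].dropna().to_numpy()
                b = table.loc[table[group_col] == gb, var].dropna().to_numpy()
                stat, p = rank_sum_test(a, b)
                qa = np.quantile(a, [0.25, 0.5, 0.75])
                qb = np.quantile(b, [0.25, 0.5, 0.75])
                comps.append(
                    GroupComparison(
                        variable=var,
                        group_a=ga,
                        group_b=gb,
                        median_a=qa[1],
                        q1_a=qa[0],
                        q3_a=qa[2],
                        median_b=qb[1],
                        q1_b=qb[0],
                        q3_b=qb[2],
                        statistic=stat,
                        p_raw=p,
                    )
                )
    adj = bh_fdr([c.p_raw for c in comps])
    rows = []
    for c, p_fdr in zip(comps, adj):
        d = c.__dict__.copy()
        d["p_fdr"] = float(p_fdr)
        d["significant"] = bool(p_fdr < alpha)
        rows.append(d)
    return pd.DataFrame(rows)


def correlate(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlation table for (parameter, index) column pairs."""
    rows = []
    for a, b in pairs:
        sub = table[[a, b]].dropna()
        r, p = pearson_correlation(sub[a], sub[b], method=method)
        rows.append({"parameter": a, "index": b, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)
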