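"""Cohort statistics: Spearman correlation matrices and Mann-Whitney tests.

Spearman rho uses average ranks (tie-corrected) with the t-distribution
p-value approximation, pairwise-complete over missing cells.  The
Mann-Whitney comparison enumerates the exact permutation null when both
groups have at most ``exact_max_n`` observations (which handles ties
correctly) and otherwise falls back to the tie-corrected normal
approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

UVEAL_GENOTYPES = ("GNAQ/GNA11",)


@dataclass
class CorrelationMatrix:
    """Marker-by-marker Spearman correlations with p-values and pair sizes.

    Pairs with fewer than ``min_n`` complete observations, or with a
    constant column, carry NaN rho and are listed in ``undefined_pairs``
    rather than silently reported as zero.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined_pairs: list


@dataclass
class GroupComparison:
    marker: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # Mann-Whitney U of group a
    p_value: float
    method: str  # "exact" | "asymptotic"


def spearman_matrix(
    table: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
    min_n: int = 4,
) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix over the given columns."""
    cols = list(columns) if columns is not None else list(table.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    undefined = []
    for i in range(k):
        n.iloc[i, i] = int(table[cols[i]].notna().sum())
    for i, j in combinations(range(k), 2):
        a = pd.to_numeric(table[cols[i]], errors="coerce")
        b = pd.to_numeric(table[cols[j]], errors="coerce")
        mask = a.notna() & b.notna()
        m = int(mask.sum())
        n.iloc[i, j] = n.iloc[j, i] = m
        if m < min_n:
            undefined.append((cols[i], cols[j], "too few complete pairs"))
            rho.iloc[i, j] = rho.iloc[j, i] = np.nan
            continue
        av, bv = a[mask].to_numpy(), b[mask].to_numpy()
        if np.all(av == av[0]) or np.all(bv == bv[0]):
            undefined.append((cols[i], cols[j], "constant column"))
            rho.iloc[i, j] = rho.iloc[j, i] = np.nan
            continue
        res = sps.spearmanr(av, bv)
        rho.iloc[i, j] = rho.iloc[j, i] = float(res.statistic)
        p.iloc[i, j] = p.iloc[j, i] = float(res.pvalue)
    return CorrelationMatrix(rho=rho, p=p, n=n, undefined_pairs=undefined)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def exact_mann_whitney_p(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided permutation p-value of the Mann-Whitney U statistic.

    Enumerates every assignment of the pooled observations to the two
    groups; correct in the presence of ties.  Returns ``(U_a, p)`` with the
    two-sided p as twice the smaller tail (capped at 1), equality included
    in both tails.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a)
    lower = upper = total = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        u = _u_statistic(ranks[list(idx)], n_a)
        total += 1
        if u <= u_obs + eps:
            lower += 1
        if u >= u_obs - eps:
            upper += 1
    p = min(1.0, 2.0 * min(lower, upper) / total)
    return u_obs, p


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    marker: str = "",
    group_a: str = "a",
    group_b: str = "b",
    exact_max_n: int = 8,
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of two independent groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        u, p = exact_mann_whitney_p(a, b)
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        method = "asymptotic"
    return GroupComparison(marker=marker, group_a=group_a, group_b=group_b,
                           n_a=int(a.size), n_b=int(b.size),
                           statistic=u, p_value=p, method=method)


def compare_groups(
    cohort: pd.DataFrame,
    which: str = "pre",
    markers: Optional[Sequence[str]] = None,
    exact_max_n: int = 8,
) -> list[GroupComparison]:
    """Cutaneous-vs-uveal Mann-Whitney comparison per marker.

    ``cohort`` is an ingested cohort table with a ``genotype`` column;
    GNAQ/GNA11 lines form the uveal group, all others the cutaneous group.
    ``which`` selects the ``_pre`` (baseline) or ``_post`` condition columns.
    """
    if which not in ("pre", "post"):
        raise ValueError("which must be 'pre' or 'post'")
    if "genotype" not in cohort.columns:
        raise ValueError("cohort table lacks a genotype column")
    if cohort["genotype"].isna().any() or (cohort["genotype"] == "").any():
        raise ValueError("every line must carry a genotype label")
    if markers is None:
        suffix = f"_{which}"
        markers = [c[: -len(suffix)] for c in cohort.columns
                   if c.endswith(suffix)]
    uveal_mask = cohort["genotype"].isin(UVEAL_GENOTYPES)
    results = []
    for m in markers:
        col = f"{m}_{which}"
        values = pd.to_numeric(cohort[col], errors="coerce")
        cut = values[~uveal_mask].dropna()
        uvm = values[uveal_mask].dropna()
        results.append(mann_whitney(
            cut, uvm, marker=m, group_a="cutaneous", group_b="uveal",
            exact_max_n=exact_max_n))
    return results
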