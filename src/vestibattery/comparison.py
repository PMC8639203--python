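"""Item-wise nonparametric screening across the four diagnostic groups.

The screening stage mirrors standard practice for non-normal clinical
variables: a Kruskal–Wallis omnibus test per item across PPPD, CDA, UVH
and UD, followed — only for omnibus-significant items — by Dunn's
post-hoc pairwise z-tests on the pooled midranks with Bonferroni
correction over the six group pairs. Two-sample comparisons for the
vHIT sub-cohort use Mann–Whitney for continuous variables and Fisher's
exact test for 2x2 tables.

Dunn's test is implemented here directly (pooled midranks, tie
correction ``sum(t^3 - t) / (12 (N - 1))``, two-sided normal p values
multiplied by the number of pairs and capped at 1).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "fisher_exact_2x2",
    "mann_whitney",
    "compare_all_items",
    "TABLE_ITEMS",
]

logger = logging.getLogger(__name__)

DISEASES = ("PPPD", "CDA", "UVH", "UD")

#: the demographic, questionnaire and vestibular-test items screened
TABLE_ITEMS = (
    "age",
    "HADS_anxiety", "HADS_depression", "HADS_total",
    "DHI_physical", "DHI_emotional", "DHI_functional", "DHI_total",
    "NPQ_upright", "NPQ_movement", "NPQ_visual", "NPQ_total",
    "CP_percent", "DP_percent",
    "cvemp_iaar", "ovemp_iaar",
    "foam_ratio", "romberg_ratio_foam",
    "vor_dp_percent",
)


@dataclass
class ComparisonResult:
    """Kruskal–Wallis result for one item, with optional Dunn post-hoc."""

    item: str
    H: float
    df: int
    p_kw: float
    pairwise: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    significant_overall: bool = False
    significant_pairs: set[tuple[str, str]] = field(default_factory=set)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal–Wallis H on midranks with tie correction.

    Returns ``(H, df, p)`` with ``df = k - 1`` and p from the chi-square
    approximation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    if all(np.all(a == arrays[0][0]) for a in arrays):
        # scipy raises on all-identical data; H is 0 by definition
        return 0.0, len(arrays) - 1, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), len(arrays) - 1, float(res.pvalue)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Dunn's pairwise post-hoc z-tests with Bonferroni correction.

    All groups are ranked jointly (midranks); for each pair the statistic

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),

    with tie term ``T = sum(t^3 - t) / (12 (N - 1))``, is referred to the
    standard normal; two-sided p values are multiplied by the number of
    pairs and capped at 1.

    Returns a mapping (label_i, label_j) -> (z, p_adjusted).
    """
    if len(groups) < 3:
        raise ValueError("Dunn post-hoc requires at least three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    if labels is None:
        labels = [str(i) for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(float(np.mean(ranks[start : start + a.size])))
        sizes.append(a.size)
        start += a.size

    n_pairs = comb(len(arrays), 2)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for i, j in combinations(range(len(arrays)), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:  # all observations tied everywhere
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p_raw = 2.0 * stats.norm.sf(abs(z))
        out[(labels[i], labels[j])] = (float(z), float(min(1.0, n_pairs * p_raw)))
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Computed by hypergeometric enumeration with margins fixed: the sum of
    point probabilities of all tables no more probable than the observed
    one (relative tolerance 1e-12 on the probability comparison).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    if n_total == 0:
        raise ValueError("table is empty")
    row1 = a + b
    col1 = a + c
    dist = stats.hypergeom(n_total, col1, row1)
    support = np.arange(max(0, row1 + col1 - n_total), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    return float(min(1.0, np.sum(pmf[pmf <= p_obs * (1 + 1e-12)])))


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(np.sum(ranks[: x.size]) - x.size * (x.size + 1) / 2.0)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration over all ``C(n1+n2, n1)`` labelings (midrank U,
    two-sided p as the permutation probability of a deviation from
    ``n1 n2 / 2`` at least as large as observed) when ``n1 + n2 <= 12``;
    otherwise the normal approximation with tie correction (scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u_obs = _mann_whitney_u(x, y)
    if x.size + y.size <= 12:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        offset = x.size * (x.size + 1) / 2.0
        mu = x.size * y.size / 2.0
        dev = abs(u_obs - mu) - 1e-12
        hits = total = 0
        for idx in combinations(range(pooled.size), x.size):
            u = float(np.sum(ranks[list(idx)]) - offset)
            hits += abs(u - mu) >= dev
            total += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def compare_all_items(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    items: Sequence[str] = TABLE_ITEMS,
    min_per_group: int = 2,
) -> tuple[list[ComparisonResult], list[str]]:
    """Kruskal–Wallis screening of every item, Dunn post-hoc on the hits.

    Each item uses its available (non-missing) values per group; the
    "other" stratum is excluded. Items with fewer than ``min_per_group``
    values in any group are skipped with a warning. Dunn's test runs only
    for items with omnibus p < ``alpha``; the returned shortlist contains
    the items with at least one Bonferroni-significant pair.
    """
    results: list[ComparisonResult] = []
    shortlist: list[str] = []
    for item in items:
        groups = [
            cohort.loc[cohort["true_diagnosis"] == g, item].dropna().to_numpy()
            for g in DISEASES
        ]
        if any(g.size < min_per_group for g in groups):
            logger.warning("item %s skipped: fewer than %d values in a group", item, min_per_group)
            continue
        h, df_, p = kruskal_wallis(groups)
        res = ComparisonResult(item=item, H=h, df=df_, p_kw=p,
                               significant_overall=p < alpha)
        if res.significant_overall:
            res.pairwise = dunn_posthoc(groups, labels=list(DISEASES))
            res.significant_pairs = {
                pair for pair, (_, p_adj) in res.pairwise.items() if p_adj < alpha
            }
            if res.significant_pairs:
                shortlist.append(item)
        results.append(res)
    return results, shortlist
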