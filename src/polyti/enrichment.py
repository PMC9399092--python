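"""Over-representation testing of gene sets against category annotations.

One-sided hypergeometric tests (the classic GO over-representation test)
with Bonferroni control over the categories actually tested. The universe
is supplied by the caller — in this pipeline the expression-filtered gene
set of the comparison, not the whole genome. GO-graph propagation is out
of scope: the category map is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import ParameterError


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N and k >= 0):
        raise ParameterError(
            f"inconsistent hypergeometric counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    k: int  # hits in the query set
    n: int  # query-set size
    K: int  # category size in the universe
    N: int  # universe size
    p_raw: float
    p_adj: float
    significant: bool


def enrich(
    gene_set: Iterable[str],
    universe: Iterable[str],
    category_map: Mapping[str, Iterable[str]] | pd.DataFrame,
    alpha: float = 0.001,
    correction: str = "bonferroni",
    min_category_size: int = 3,
) -> list[EnrichmentResult]:
    """Test every category for over-representation in the gene set.

    ``category_map`` maps category -> genes, or is a two-column DataFrame
    (gene_id, category). Categories are restricted to the universe; only
    those with at least ``min_category_size`` universe members are tested,
    and the Bonferroni factor m is the number tested. Significance is
    strict: p_adj < alpha. Results are sorted by adjusted p (category name
    breaking ties).
    """
    genes = set(gene_set)
    uni = set(universe)
    stray = genes - uni
    if stray:
        raise ParameterError(
            f"genes in set but not in universe: {sorted(stray)[:5]}"
        )
    if correction not in ("bonferroni", "none"):
        raise ParameterError(f"unknown correction: {correction}")
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    if isinstance(category_map, pd.DataFrame):
        gcol, ccol = category_map.columns[:2]
        category_map = {
            cat: set(sub[gcol]) for cat, sub in category_map.groupby(ccol)
        }
    testable = {
        cat: set(members) & uni
        for cat, members in category_map.items()
        if len(set(members) & uni) >= min_category_size
    }
    m = len(testable)
    results = []
    for cat, members in testable.items():
        k = len(members & genes)
        p = hypergeom_tail(k, len(members), len(genes), len(uni))
        p_adj = min(1.0, m * p) if correction == "bonferroni" else p
        results.append(
            EnrichmentResult(
                category=cat,
                k=k,
                n=len(genes),
                K=len(members),
                N=len(uni),
                p_raw=p,
                p_adj=p_adj,
                significant=p_adj < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.category))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
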