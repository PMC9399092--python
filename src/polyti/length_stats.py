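"""ORF-length stratified statistics for differential-translation calls.

Long open reading frames are the covariate of interest: strains expressing
the uL30B paralog shift translation toward long ORFs. This module provides
the Mann-Whitney U comparison used for length distributions (exact by full
enumeration for small samples, tie-corrected normal approximation
otherwise), top-N length summaries of the strongest calls, length-binned
B/A TI ratios, and the TI-length rank correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io import GeneAnnotation
from .ti import DifferentialCalls, Group, TITable

#: largest C(n+m, n) for which the exact enumeration is attempted
EXACT_MAX_COMBINATIONS = 200_000


@dataclass(frozen=True)
class LengthComparison:
    """Result of a two-sample Mann-Whitney comparison."""

    label_x: str
    label_y: str
    n_x: int
    n_y: int
    median_x: float
    median_y: float
    u: float
    p_value: float
    mode: str  # "exact" or "normal_approx"


def _u_statistic(ranks: np.ndarray, idx_x: np.ndarray, n_x: int) -> float:
    return ranks[idx_x].sum() - n_x * (n_x + 1) / 2.0


def mann_whitney(
    x,
    y,
    alternative: str = "two_sided",
    mode: str = "auto",
    labels: tuple[str, str] = ("x", "y"),
) -> LengthComparison:
    """Mann-Whitney U test with midranks for ties.

    ``mode='exact'`` enumerates all C(n+m, n) assignments of the pooled
    observations to the first sample (valid with ties); ``'auto'`` uses the
    enumeration while C(n+m, n) <= 200,000 and otherwise the tie-corrected
    normal approximation with continuity correction. The two-sided exact p
    counts assignments whose U is at least as far from the null mean nm/2
    as the observed U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("Mann-Whitney requires two nonempty samples")
    if alternative not in ("two_sided", "less", "greater"):
        raise ParameterError(f"unknown alternative: {alternative}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks, np.arange(n), n)

    n_comb = math.comb(n + m, n)
    if mode == "auto":
        mode = "exact" if n_comb <= EXACT_MAX_COMBINATIONS else "normal_approx"
    if mode == "exact" and n_comb > EXACT_MAX_COMBINATIONS:
        raise ParameterError(
            f"exact enumeration infeasible: C({n + m},{n}) = {n_comb}"
        )

    if mode == "exact":
        mu = n * m / 2.0
        eps = 1e-9
        hits = 0
        for idx in combinations(range(n + m), n):
            u = _u_statistic(ranks, np.array(idx), n)
            if alternative == "two_sided":
                hits += abs(u - mu) >= abs(u_obs - mu) - eps
            elif alternative == "greater":
                hits += u >= u_obs - eps
            else:
                hits += u <= u_obs + eps
        p = hits / n_comb
    elif mode == "normal_approx":
        scipy_alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
        res = stats.mannwhitneyu(
            x, y, alternative=scipy_alt[alternative], method="asymptotic"
        )
        p = float(res.pvalue)
    else:
        raise ParameterError(f"unknown mode: {mode}")
    return LengthComparison(
        label_x=labels[0],
        label_y=labels[1],
        n_x=n,
        n_y=m,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
        u=float(u_obs),
        p_value=min(float(p), 1.0),
        mode=mode,
    )


@dataclass(frozen=True)
class LengthSummary:
    """ORF-length summary of over- vs under-translated calls."""

    top_n: int
    over_top_mean: float
    over_top_median: float
    under_top_mean: float
    under_top_median: float
    mean_ratio: float  # over-top mean / under-top mean
    over_vs_all: LengthComparison
    under_vs_all: LengthComparison
    over_vs_under: LengthComparison


def _top_by_magnitude(calls: DifferentialCalls, side: str, top_n: int) -> pd.Index:
    genes = calls.over if side == "over" else calls.under
    if len(genes) == 0:
        raise ParameterError(f"no {side}-translated genes to summarize")
    if len(genes) < top_n:
        warnings.warn(
            f"only {len(genes)} {side}-translated genes; shrinking top_n from "
            f"{top_n}",
            stacklevel=3,
        )
        top_n = len(genes)
    mag = calls.table.loc[genes, "delta_log2_ti"].abs()
    # magnitude descending, gene_id as the deterministic tiebreak
    order = sorted(genes, key=lambda g: (-mag[g], g))
    return pd.Index(order[:top_n])


def length_summary(
    calls: DifferentialCalls, annotation: GeneAnnotation, top_n: int = 20
) -> LengthSummary:
    """Compare ORF lengths of the strongest over- and under-translated genes.

    Top-N genes per side are ranked by |delta log2 TI| (gene id breaks
    ties). Besides the top-N means/medians and their over/under ratio, the
    full called sets are each compared against the all-gene length
    distribution, and against each other, by Mann-Whitney.
    """
    lengths = annotation.lengths()
    top_over = _top_by_magnitude(calls, "over", top_n)
    top_under = _top_by_magnitude(calls, "under", top_n)
    all_lengths = lengths.reindex(calls.genes).dropna()
    over_lengths = lengths.reindex(calls.over).dropna()
    under_lengths = lengths.reindex(calls.under).dropna()
    return LengthSummary(
        top_n=min(top_n, len(top_over), len(top_under)),
        over_top_mean=float(lengths.reindex(top_over).mean()),
        over_top_median=float(lengths.reindex(top_over).median()),
        under_top_mean=float(lengths.reindex(top_under).mean()),
        under_top_median=float(lengths.reindex(top_under).median()),
        mean_ratio=float(
            lengths.reindex(top_over).mean() / lengths.reindex(top_under).mean()
        ),
        over_vs_all=mann_whitney(over_lengths, all_lengths, labels=("over", "all")),
        under_vs_all=mann_whitney(under_lengths, all_lengths, labels=("under", "all")),
        over_vs_under=mann_whitney(
            over_lengths, under_lengths, labels=("over", "under")
        ),
    )


def ti_ratio_by_length_bin(
    ti: TITable,
    group_b: Group,
    group_a: Group,
    annotation: GeneAnnotation,
    bin_edges,
    min_genes: int = 10,
) -> pd.DataFrame:
    """Mean log2(TI_b / TI_a) within ORF-length bins.

    Genes are assigned to [edge_i, edge_{i+1}) bins by ORF length; bins
    holding fewer than ``min_genes`` genes are flagged (``sparse`` column)
    but still reported.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 3:
        raise ParameterError("need at least 2 bins (3 edges)")
    if not np.all(np.diff(edges) > 0):
        raise ParameterError("bin edges must be strictly increasing")
    log2 = ti.log2
    for g in (group_b, group_a):
        if tuple(g) not in ti.groups:
            raise ParameterError(f"group {g} absent from TI table")
    delta = log2[tuple(group_b)] - log2[tuple(group_a)]
    lengths = annotation.lengths().reindex(delta.index)
    keep = lengths.notna()
    delta, lengths = delta[keep], lengths[keep]
    which = np.digitize(lengths, edges, right=False) - 1
    rows = []
    for i in range(edges.size - 1):
        sel = which == i
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo_nt": edges[i],
                "bin_hi_nt": edges[i + 1],
                "n_genes": n,
                "mean_delta_log2": float(delta[sel].mean()) if n else np.nan,
                "sparse": n < min_genes,
            }
        )
    return pd.DataFrame(rows)


def ti_length_correlation(
    ti: TITable,
    annotation: GeneAnnotation,
    group: Group | None = None,
    density: bool = False,
) -> tuple[float, float]:
    """Spearman correlation between log2 TI and log ORF length.

    With ``density=True`` the TI is divided by ORF length first (a per-nt
    ribosome-loading proxy). When ``group`` is None and the table holds a
    single group, that group is used.
    """
    if group is None:
        if len(ti.groups) != 1:
            raise ParameterError("group must be given for a multi-group TI table")
        group = ti.groups[0]
    values = ti.ti[tuple(group)]
    lengths = annotation.lengths().reindex(values.index).astype(float)
    keep = lengths.notna()
    values, lengths = values[keep], lengths[keep]
    if values.size < 10:
        raise ParameterError("need >= 10 genes for a rank correlation")
    signal = np.log2(values / lengths) if density else np.log2(values)
    if np.all(signal == signal.iloc[0]) or np.all(lengths == lengths.iloc[0]):
        raise ParameterError("constant input: correlation undefined")
    rho, p = stats.spearmanr(signal, np.log(lengths))
    return float(rho), float(p)
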