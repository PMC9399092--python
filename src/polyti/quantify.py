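"""Per-sample normalization of fraction counts and the expression filter.

Total-RNA samples are quantified in TPM (length-aware: reads are first
divided by ORF length, then scaled to a million); polysome-fraction samples
destined for the translation index are quantified in CPM (length-blind).
No between-sample normalization beyond the per-column scaling is applied —
the translation index is a within-gene ratio of fractions and extra
normalization would silently distort it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import NormalizationError, ParameterError
from .io import FractionCounts, GeneAnnotation


@dataclass(frozen=True)
class ExpressionTable:
    """Gene x sample matrix of nonnegative reals with a unit tag (TPM/CPM)."""

    values: pd.DataFrame
    unit: str  # "TPM" or "CPM"

    def __post_init__(self):
        if self.unit not in ("TPM", "CPM"):
            raise ParameterError(f"unknown expression unit: {self.unit}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def normalize(
    counts: FractionCounts,
    method: str,
    lengths: pd.Series | GeneAnnotation | None = None,
) -> ExpressionTable:
    """Normalize a count matrix to TPM or CPM.

    CPM_gs = counts_gs / colsum_s * 1e6
    TPM_gs = (counts_gs / length_g) / sum_g(counts_gs / length_g) * 1e6

    TPM lengths are ORF lengths in nucleotides, taken from the annotation.
    """
    method = method.lower()
    if method not in ("tpm", "cpm"):
        raise ParameterError(f"unknown normalization method: {method}")
    mat = counts.counts.astype(float)
    zero = mat.sum(axis=0) == 0
    if zero.any():
        raise NormalizationError(
            f"all-zero sample column(s): {sorted(mat.columns[zero])}"
        )
    if method == "cpm":
        vals = mat.div(mat.sum(axis=0), axis=1) * 1e6
        return ExpressionTable(vals, "CPM")
    if lengths is None:
        raise ParameterError("TPM normalization requires gene lengths")
    if isinstance(lengths, GeneAnnotation):
        lengths = lengths.lengths()
    lengths = lengths.reindex(mat.index)
    if lengths.isna().any():
        missing = sorted(mat.index[lengths.isna()])[:5]
        raise ParameterError(f"missing ORF length for genes: {missing}")
    if (lengths <= 0).any():
        raise ParameterError("ORF lengths must be positive")
    rate = mat.div(lengths.astype(float), axis=0)
    vals = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return ExpressionTable(vals, "TPM")


def filter_expressed(
    expr: ExpressionTable, min_tpm: float, scope: Iterable[str]
) -> pd.Index:
    """Genes whose mean TPM across the scope samples is strictly > min_tpm.

    The strict inequality mirrors the "expression > 1 TPM" gene universe:
    a gene sitting exactly at the threshold is excluded.
    """
    scope = list(scope)
    if not scope:
        raise ParameterError("expression-filter scope is empty")
    missing = sorted(set(scope) - set(expr.samples))
    if missing:
        raise ParameterError(f"scope samples absent from table: {missing}")
    mean = expr.values[scope].mean(axis=1)
    return expr.genes[np.asarray(mean) > min_tpm]
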