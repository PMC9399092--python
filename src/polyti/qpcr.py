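"""qPCR relative quantification and proteomics acetylation summaries.

Relative quantity follows the comparative-Ct formula with amplification
efficiency fixed at 2:

    RQ = 2^(Ct_Reference - Ct_Test)_Gene / 2^(Ct_Reference - Ct_Test)_Control

Technical replicates are averaged on the Ct scale before exponentiation.
A qPCR translation index divides the gene's heavy-fraction signal by its
light-fraction signal, normalized to a control transcript measured in the
same fractions (Osh6 mRNA or Nme1 ncRNA in the original assays).

Proteomics summaries operate on summed N-terminal peptide intensities
classified as acetylated or not; percentages and paralog ratios are
computed within samples, so no between-sample normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import FormatError, MeasurementMissingError, ParameterError

CT_COLUMNS = ("sample_id", "condition_label", "gene_id", "ct", "tech_rep")
PEPTIDE_COLUMNS = ("sample_id", "paralog", "acetylated", "fraction", "intensity")


def read_ct_table(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"Ct table missing columns: {missing}", path=path)
    if (t["ct"] <= 0).any():
        raise FormatError("Ct values must be positive", path=path, field="ct")
    return t


def read_peptide_table(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    missing = [c for c in PEPTIDE_COLUMNS if c not in t.columns]
    if missing:
        raise FormatError(f"peptide table missing columns: {missing}", path=path)
    if (t["intensity"] < 0).any():
        raise FormatError("intensities must be >= 0", path=path, field="intensity")
    return t


def _mean_ct(ct: pd.DataFrame, sample: str, gene: str) -> float:
    rows = ct[(ct["sample_id"] == sample) & (ct["gene_id"] == gene)]
    if rows.empty:
        raise MeasurementMissingError(f"no Ct well for (sample={sample!r}, gene={gene!r})")
    return float(rows["ct"].mean())


def relative_quantity(
    ct: pd.DataFrame,
    gene: str,
    control_gene: str,
    reference_sample: str,
    test_sample: str,
) -> float:
    """Comparative-Ct RQ of a gene between two samples, control-normalized."""
    d_gene = _mean_ct(ct, reference_sample, gene) - _mean_ct(ct, test_sample, gene)
    d_ctrl = _mean_ct(ct, reference_sample, control_gene) - _mean_ct(
        ct, test_sample, control_gene
    )
    return float(2.0**d_gene / 2.0**d_ctrl)


def _pooled_ct(ct: pd.DataFrame, samples: Sequence[str], gene: str) -> float:
    """Mean of per-sample mean Cts across a set of fraction samples."""
    if not samples:
        raise ParameterError("empty sample list")
    return float(np.mean([_mean_ct(ct, s, gene) for s in samples]))


def qpcr_translation_index(
    ct: pd.DataFrame,
    gene: str,
    control_gene: str,
    heavy_samples: Sequence[str],
    light_samples: Sequence[str],
) -> float:
    """Translation index from fraction-resolved qPCR.

    Heavy/light amount ratio of the gene (2^(Ct_light - Ct_heavy)) divided
    by the same ratio for the control transcript; equivalent to
    ``relative_quantity`` with the light fraction as reference and the
    heavy fraction as test.
    """
    d_gene = _pooled_ct(ct, light_samples, gene) - _pooled_ct(ct, heavy_samples, gene)
    d_ctrl = _pooled_ct(ct, light_samples, control_gene) - _pooled_ct(
        ct, heavy_samples, control_gene
    )
    return float(2.0**d_gene / 2.0**d_ctrl)


# ---------------------------------------------------------------------------
# Proteomics


def _summed_intensity(
    peptides: pd.DataFrame,
    sample: str,
    paralog: str,
    acetylated: bool | None = None,
    fraction: str | None = None,
) -> float:
    rows = peptides[
        (peptides["sample_id"] == sample) & (peptides["paralog"] == paralog)
    ]
    if fraction is not None:
        rows = rows[rows["fraction"] == fraction]
    if acetylated is not None:
        sub = rows[rows["acetylated"] == acetylated]
        if sub.empty and not rows.empty:
            warnings.warn(
                f"no {'acetylated' if acetylated else 'non-acetylated'} rows for "
                f"(sample={sample!r}, paralog={paralog!r}); treating as 0",
                stacklevel=3,
            )
        rows = sub
    return float(rows["intensity"].sum())


def percent_acetylation(
    peptides: pd.DataFrame, sample: str, paralog: str, fraction: str | None = None
) -> float:
    """Acetylated share of summed N-terminal peptide intensity, in percent."""
    ac = _summed_intensity(peptides, sample, paralog, True, fraction)
    non = _summed_intensity(peptides, sample, paralog, False, fraction)
    total = ac + non
    if total <= 0:
        raise MeasurementMissingError(
            f"zero total N-terminal intensity for (sample={sample!r}, "
            f"paralog={paralog!r})"
        )
    return 100.0 * ac / total


def percent_non_acetylation(
    peptides: pd.DataFrame, sample: str, paralog: str, fraction: str | None = None
) -> float:
    """Exact complement of ``percent_acetylation`` (they sum to 100)."""
    return 100.0 - percent_acetylation(peptides, sample, paralog, fraction)


def paralog_ratio(
    peptides: pd.DataFrame,
    sample: str,
    numerator: str = "A",
    denominator: str = "B",
    fraction: str | None = None,
    numerator_acetylated: bool | None = None,
    denominator_acetylated: bool | None = None,
) -> float:
    """Within-sample ratio of summed paralog intensities (default A over B).

    Acetyl-state restriction supports the polysome-resolved variant (e.g.
    non-acetylated A over acetylated B per gradient fraction).
    """
    num = _summed_intensity(peptides, sample, numerator, numerator_acetylated, fraction)
    den = _summed_intensity(
        peptides, sample, denominator, denominator_acetylated, fraction
    )
    if den <= 0:
        raise MeasurementMissingError(
            f"zero denominator intensity for paralog {denominator!r} in "
            f"sample {sample!r}"
        )
    return num / den
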