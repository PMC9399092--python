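"""Translation index computation and differential-translation calls.

The translation index (TI) of a gene is the ratio of its mRNA in heavy
polysome fractions (tetrasome and heavier) to its mRNA in light fractions
(40S, 60S, 80S), computed from CPM-normalized fraction counts. Genes whose
log2 TI differs between two strains/conditions by strictly more than a
threshold (default log2 0.5) are called over- or under-translated; genes
called in opposite directions in two comparisons are "inversely regulated".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, MeasurementMissingError, PairingError, ParameterError
from .io import AnalysisConfig, SampleManifest
from .quantify import ExpressionTable

Group = tuple[str, str]  # (strain, condition)


@dataclass(frozen=True)
class TITable:
    """Per-gene linear TI for each (strain, condition) group.

    ``ti`` has a MultiIndex column per group; ``flags`` marks genes with
    zero counts in both fractions of at least one replicate of the group
    (they are flagged, never dropped).
    """

    ti: pd.DataFrame
    flags: pd.DataFrame
    replicate_combine: str
    pseudocount: float

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.ti)

    @property
    def groups(self) -> list[Group]:
        return list(self.ti.columns)

    def to_long(self) -> pd.DataFrame:
        """Long (gene, strain, condition, ti, log2_ti) table for output."""
        long = self.ti.stack([0, 1], future_stack=True).rename("ti").reset_index()
        long.columns = ["gene_id", "strain", "condition", "ti"]
        long["log2_ti"] = np.log2(long["ti"])
        return long

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "TITable":
        wide = long.pivot(index="gene_id", columns=["strain", "condition"], values="ti")
        flags = pd.DataFrame(False, index=wide.index, columns=wide.columns)
        return cls(wide, flags, "unknown", float("nan"))


def compute_ti(
    expr: ExpressionTable, manifest: SampleManifest, config: AnalysisConfig
) -> TITable:
    """Per-gene TI for every (strain, condition) group with heavy+light samples.

    Per replicate r: TI_g = (CPM_heavy_g + pc) / (CPM_light_g + pc).
    Replicates are combined as the mean of log2 TI (default) or by summing
    CPM across replicates before the ratio (``pooled_counts``).
    """
    if expr.unit != "CPM":
        raise ParameterError("compute_ti requires CPM-normalized expression")
    pc = config.pseudocount
    cols: dict[Group, pd.Series] = {}
    flag_cols: dict[Group, pd.Series] = {}
    for strain, condition in manifest.groups():
        heavy = manifest.samples(strain, condition, "heavy")
        light = manifest.samples(strain, condition, "light")
        if heavy.empty or light.empty:
            if heavy.empty and light.empty:
                continue  # e.g. a total-RNA-only group
            raise PairingError(
                f"group ({strain}, {condition}) lacks a "
                f"{'heavy' if heavy.empty else 'light'} fraction"
            )
        h_by_rep = dict(zip(heavy["replicate"], heavy["sample_id"]))
        l_by_rep = dict(zip(light["replicate"], light["sample_id"]))
        reps = sorted(set(h_by_rep) & set(l_by_rep))
        if not reps:
            raise PairingError(
                f"group ({strain}, {condition}) has no replicate with both "
                "heavy and light samples"
            )
        h = expr.values[[h_by_rep[r] for r in reps]].to_numpy()
        l = expr.values[[l_by_rep[r] for r in reps]].to_numpy()
        flag_cols[(strain, condition)] = pd.Series(
            ((h == 0) & (l == 0)).any(axis=1), index=expr.genes
        )
        if pc == 0 and ((h == 0) | (l == 0)).any():
            warnings.warn(
                "zero CPM with pseudocount 0 yields zero/infinite TI",
                stacklevel=2,
            )
        per_rep = (h + pc) / (l + pc)
        if config.replicate_combine == "mean_log2":
            combined = 2.0 ** np.log2(per_rep).mean(axis=1)
        else:  # pooled_counts
            combined = (h.sum(axis=1) + pc) / (l.sum(axis=1) + pc)
        cols[(strain, condition)] = pd.Series(combined, index=expr.genes)
    if not cols:
        raise PairingError("no (strain, condition) group has heavy and light samples")
    ti = pd.DataFrame(cols)
    ti.columns = pd.MultiIndex.from_tuples(ti.columns, names=["strain", "condition"])
    flags = pd.DataFrame(flag_cols)
    flags.columns = ti.columns
    return TITable(ti, flags, config.replicate_combine, pc)


@dataclass(frozen=True)
class DifferentialCalls:
    """Per-gene delta log2 TI (test - reference) and the resulting call."""

    table: pd.DataFrame  # columns: delta_log2_ti, call
    threshold: float
    test_group: Group
    ref_group: Group

    @property
    def over(self) -> pd.Index:
        return self.table.index[self.table["call"] == "over_translated"]

    @property
    def under(self) -> pd.Index:
        return self.table.index[self.table["call"] == "under_translated"]

    @property
    def genes(self) -> pd.Index:
        return self.table.index


def differential_ti(
    ti: TITable,
    test_group: Group,
    ref_group: Group,
    threshold: float = 0.5,
    genes: pd.Index | None = None,
) -> DifferentialCalls:
    """Call over/under-translated genes between two groups.

    delta = log2 TI(test) - log2 TI(reference); a gene is over-translated
    when delta > threshold, under-translated when delta < -threshold — the
    inequalities are strict ("more than" the threshold), so a gene sitting
    exactly at +/-threshold is unchanged.
    """
    if threshold <= 0:
        raise ParameterError("differential threshold must be > 0")
    for g in (test_group, ref_group):
        if tuple(g) not in ti.groups:
            raise ParameterError(f"group {g} absent from TI table")
    log2 = ti.log2
    delta = log2[tuple(test_group)] - log2[tuple(ref_group)]
    if genes is not None:
        missing = sorted(set(genes) - set(delta.index))
        if missing:
            raise AlignmentError(f"genes absent from TI table: {missing[:5]}")
        delta = delta.loc[list(genes)]
    call = pd.Series("unchanged", index=delta.index, dtype=object)
    call[delta > threshold] = "over_translated"
    call[delta < -threshold] = "under_translated"
    table = pd.DataFrame({"delta_log2_ti": delta, "call": call})
    return DifferentialCalls(table, threshold, tuple(test_group), tuple(ref_group))


def inverse_regulation(
    calls_a: DifferentialCalls, calls_b: DifferentialCalls
) -> pd.Index:
    """Genes called in opposite directions in two comparisons.

    Either orientation counts: over in A and under in B, or under in A and
    over in B. The two call sets must share a gene universe.
    """
    if set(calls_a.genes) != set(calls_b.genes):
        raise AlignmentError("differential-call tables have different gene universes")
    a = calls_a.table["call"]
    b = calls_b.table["call"].reindex(a.index)
    opposite = ((a == "over_translated") & (b == "under_translated")) | (
        (a == "under_translated") & (b == "over_translated")
    )
    return a.index[opposite]


def relative_enrichment(
    quantities: pd.DataFrame, gene: str, control_gene: str
) -> pd.Series:
    """Per-fraction enrichment of a gene relative to a control gene.

    ``quantities`` is fraction x gene (any within-fraction quantity: CPM or
    qPCR relative quantity). E(g, f) = (q_gf / sum_f q_gf) /
    (q_cf / sum_f q_cf): the gene's share of its own signal in fraction f
    over the control's share. Identical distributions give E == 1
    everywhere; the profile is invariant to rescaling either gene.
    """
    for g in (gene, control_gene):
        if g not in quantities.columns:
            raise MeasurementMissingError(f"gene {g!r} absent from fraction table")
        if quantities[g].isna().any():
            frac = quantities.index[quantities[g].isna()][0]
            raise MeasurementMissingError(f"gene {g!r} missing in fraction {frac!r}")
    q_g = quantities[gene].astype(float)
    q_c = quantities[control_gene].astype(float)
    if q_g.sum() == 0 or q_c.sum() == 0:
        raise MeasurementMissingError("gene or control has zero total signal")
    share_g = q_g / q_g.sum()
    share_c = q_c / q_c.sum()
    return share_g / share_c
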