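"""End-to-end convenience: counts -> CPM/TPM -> TI -> calls -> summaries.

Chains the individual stages with the conventions the rest of the package
documents: the expressed-gene universe is defined by the mean TPM of the
total-RNA samples of the two compared groups (strictly > the threshold),
TI comes from CPM-normalized heavy/light fractions, and enrichment runs
against the expression-filtered universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import EnrichmentResult, enrich
from .io import AnalysisConfig, FractionCounts, GeneAnnotation, SampleManifest
from .length_stats import LengthSummary, length_summary
from .quantify import filter_expressed, normalize
from .ti import DifferentialCalls, Group, TITable, compute_ti, differential_ti


@dataclass(frozen=True)
class ComparisonResult:
    expressed: pd.Index
    ti: TITable
    calls: DifferentialCalls
    lengths: LengthSummary | None
    enrichment: list[EnrichmentResult] | None


def run_comparison(
    counts: FractionCounts,
    manifest: SampleManifest,
    annotation: GeneAnnotation,
    test_group: Group,
    ref_group: Group,
    config: AnalysisConfig | None = None,
    top_n: int = 20,
    with_lengths: bool = True,
    with_enrichment: bool = True,
) -> ComparisonResult:
    """Differential-translation comparison of two (strain, condition) groups."""
    config = config or AnalysisConfig()

    total_ids = [
        sid
        for strain, condition in (test_group, ref_group)
        for sid in manifest.samples(strain, condition, "total")["sample_id"]
    ]
    if total_ids:
        tpm = normalize(counts.subset_samples(total_ids), "tpm", annotation)
        expressed = filter_expressed(tpm, config.expression_min_tpm, total_ids)
    else:  # no total-RNA samples: fall back to the full gene universe
        expressed = counts.genes

    fraction_ids = [
        sid
        for strain, condition in (test_group, ref_group)
        for frac in ("heavy", "light")
        for sid in manifest.samples(strain, condition, frac)["sample_id"]
    ]
    sub = counts.subset_samples(fraction_ids)
    cpm = normalize(sub, "cpm")
    ti = compute_ti(cpm, sub.manifest, config)
    calls = differential_ti(
        ti, test_group, ref_group, config.ti_log2_threshold, genes=expressed
    )
    lengths = (
        length_summary(calls, annotation, top_n=top_n) if with_lengths else None
    )
    enrichment = None
    if with_enrichment:
        cat_map = annotation.category_map()
        enrichment = enrich(
            set(calls.over),
            set(calls.genes),
            cat_map,
            alpha=config.enrichment_alpha,
            correction=config.correction,
        )
    return ComparisonResult(expressed, ti, calls, lengths, enrichment)
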