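"""Readers, writers and validated containers for the pipeline's tabular inputs.

The pipeline consumes gene-by-sample integer count matrices from polysome
fractions (light = 40S/60S/80S, heavy = tetrasome and heavier, plus total-RNA
samples), a sample manifest describing strain/condition/fraction/replicate,
and a gene annotation carrying ORF length, start-codon context and category
labels. All formats are plain text: counts as TSV, manifest as CSV,
annotation as TSV or a GFF3 + genome FASTA pair.

Conventions: GFF3 coordinates are 1-based inclusive (the standard); internal
coordinates are 0-based half-open. Gene identifiers are case-preserved and
matched exactly. Numeric output is written with 6 significant digits; counts
as integers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ContextError,
    FormatError,
    ManifestError,
    ParameterError,
)

CONDITIONS = ("untreated", "treated")
CORE_FRACTIONS = ("light", "heavy", "total")
_GRADIENT_RE = re.compile(r"^gradient:[\w.+-]+$")
CONTEXT_RE = re.compile(r"^[ACGT]{6}ATG[ACGT]{3}$")

#: printf format giving 6 significant digits for all floating-point output
FLOAT_FORMAT = "%.6g"


def _valid_fraction(label: str) -> bool:
    return label in CORE_FRACTIONS or bool(_GRADIENT_RE.match(label))


@dataclass(frozen=True)
class SampleManifest:
    """Sample metadata: one row per sequencing/qPCR sample.

    Columns: sample_id (unique), strain, condition (untreated/treated),
    fraction (light/heavy/total/gradient:<name>), replicate (positive int).
    """

    table: pd.DataFrame

    COLUMNS = ("sample_id", "strain", "condition", "fraction", "replicate")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.COLUMNS if c not in t.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise ManifestError(f"duplicate sample_ids: {dups}")
        bad_cond = sorted(set(t["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise ManifestError(f"unknown condition labels: {bad_cond}")
        bad_frac = sorted(f for f in set(t["fraction"]) if not _valid_fraction(f))
        if bad_frac:
            raise ManifestError(f"unknown fraction labels: {bad_frac}")
        reps = t["replicate"]
        if not (pd.api.types.is_integer_dtype(reps) and (reps > 0).all()):
            raise ManifestError("replicate must be a positive integer")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(
        self,
        strain: str | None = None,
        condition: str | None = None,
        fraction: str | None = None,
    ) -> pd.DataFrame:
        """Rows matching the given (possibly partial) group key."""
        t = self.table
        mask = pd.Series(True, index=t.index)
        for col, val in (
            ("strain", strain),
            ("condition", condition),
            ("fraction", fraction),
        ):
            if val is not None:
                mask &= t[col] == val
        return t[mask]

    def groups(self) -> list[tuple[str, str]]:
        """Distinct (strain, condition) pairs, manifest order."""
        seen = self.table[["strain", "condition"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    @classmethod
    def read_csv(cls, path) -> "SampleManifest":
        try:
            t = pd.read_csv(path, dtype={"sample_id": str, "strain": str})
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise FormatError(f"cannot parse manifest: {exc}", path=path) from exc
        return cls(t)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass(frozen=True)
class FractionCounts:
    """Integer read counts, genes x samples, aligned to a manifest."""

    counts: pd.DataFrame  # index gene_id, columns sample_id, int64
    manifest: SampleManifest

    def __post_init__(self):
        c = self.counts
        if list(c.columns) != self.manifest.sample_ids:
            extra = sorted(set(c.columns) - set(self.manifest.sample_ids))
            if extra:
                raise ManifestError(f"count columns not in manifest: {extra}")
            missing = sorted(set(self.manifest.sample_ids) - set(c.columns))
            if missing:
                raise ManifestError(f"manifest samples missing from counts: {missing}")
            object.__setattr__(self, "counts", c[self.manifest.sample_ids])

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, sample_ids: Iterable[str]) -> "FractionCounts":
        ids = list(sample_ids)
        sub = self.manifest.table[self.manifest.table["sample_id"].isin(ids)]
        return FractionCounts(self.counts[ids], SampleManifest(sub))


def read_counts(path, manifest: SampleManifest) -> FractionCounts:
    """Read a TSV count matrix (first column gene_id) against a manifest.

    Every manifest sample must appear as a column and vice versa; entries
    must be nonnegative integers. Missing genes cannot be detected per
    sample in a dense matrix, but NA cells are rejected rather than
    zero-filled.
    """
    try:
        t = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse counts: {exc}", path=path) from exc
    if t.columns[0] != "gene_id":
        raise FormatError(
            "first column must be 'gene_id'", path=path, field=t.columns[0]
        )
    if t["gene_id"].duplicated().any():
        raise FormatError("duplicate gene_id rows", path=path, field="gene_id")
    t = t.set_index("gene_id")
    unknown = sorted(set(t.columns) - set(manifest.sample_ids))
    if unknown:
        raise ManifestError(f"count columns absent from manifest: {unknown}")
    if t.isna().any().any():
        gene = t.index[t.isna().any(axis=1)][0]
        raise FormatError(
            "missing count entry (NA) — genes must be present in every sample",
            path=path,
            field=str(gene),
        )
    for col in t.columns:
        vals = t[col]
        if not pd.api.types.is_integer_dtype(vals):
            as_float = pd.to_numeric(vals, errors="coerce")
            if as_float.isna().any() or (as_float % 1 != 0).any():
                raise FormatError(
                    "non-integer count entry", path=path, field=col
                )
            t[col] = as_float.astype(np.int64)
        if (t[col] < 0).any():
            raise FormatError("negative count entry", path=path, field=col)
    return FractionCounts(t.astype(np.int64), manifest)


def write_counts(fc: FractionCounts, path) -> None:
    out = fc.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene ORF length (nt, stop codon included), start context, labels.

    start_context is the 12-mer: 6 nt upstream + ATG + 3 nt downstream on
    the coding strand, uppercase; None when the context could not be
    determined (the gene is kept for length-based analyses).
    categories is a tuple of free-text labels (e.g. GO components).
    """

    table: pd.DataFrame  # index gene_id; orf_length_nt, start_context, categories

    def __post_init__(self):
        t = self.table
        for col in ("orf_length_nt",):
            if col not in t.columns:
                raise FormatError(f"annotation missing column {col}")
        if (t["orf_length_nt"] <= 0).any():
            bad = t.index[t["orf_length_nt"] <= 0][0]
            raise FormatError("nonpositive ORF length", field=str(bad))
        for gene, ctx in t["start_context"].items():
            if ctx is not None and not CONTEXT_RE.match(ctx):
                raise ContextError(
                    f"start context for {gene!r} does not match "
                    f"[ACGT]{{6}}ATG[ACGT]{{3}}: {ctx!r}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def lengths(self) -> pd.Series:
        return self.table["orf_length_nt"]

    def category_map(self) -> dict[str, set[str]]:
        """category -> set of gene_ids, from the annotation's labels."""
        out: dict[str, set[str]] = {}
        for gene, cats in self.table["categories"].items():
            for c in cats:
                out.setdefault(c, set()).add(gene)
        return out


def _parse_categories(raw) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return ()
    return tuple(s.strip() for s in str(raw).split(";") if s.strip())


def read_annotation(path) -> GeneAnnotation:
    """Read annotation TSV: gene_id, orf_length_nt[, start_context, categories]."""
    try:
        t = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    except Exception as exc:
        raise FormatError(f"cannot parse annotation: {exc}", path=path) from exc
    if "gene_id" not in t.columns or "orf_length_nt" not in t.columns:
        raise FormatError(
            "annotation requires gene_id and orf_length_nt columns", path=path
        )
    t = t.set_index("gene_id")
    ctx = t["start_context"] if "start_context" in t.columns else pd.Series(
        None, index=t.index, dtype=object
    )
    ctx = ctx.where(pd.notna(ctx), None).map(
        lambda s: s.upper() if isinstance(s, str) else None
    )
    cats = (
        t["categories"].map(_parse_categories)
        if "categories" in t.columns
        else pd.Series([()] * len(t), index=t.index)
    )
    table = pd.DataFrame(
        {
            "orf_length_nt": t["orf_length_nt"].astype(np.int64),
            "start_context": ctx,
            "categories": cats,
        }
    )
    return GeneAnnotation(table)


def write_annotation(ann: GeneAnnotation, path) -> None:
    out = ann.table.copy()
    out["start_context"] = out["start_context"].map(lambda s: s if s else "")
    out["categories"] = out["categories"].map(";".join)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def annotation_from_gff3(gff3_path, fasta_path) -> GeneAnnotation:
    """Derive ORF lengths and start contexts from a GFF3 + genome FASTA.

    ORF length = summed CDS length (stop codon included as annotated).
    Start context = 6 nt upstream + ATG + 3 nt downstream on the coding
    strand; minus-strand features are reverse-complemented before
    validation. Genes whose context falls off the contig or is shorter
    than required keep length information with start_context = None.
    """
    import gffutils
    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = {}
    for gene in db.features_of_type(("gene",)):
        cds = sorted(
            db.children(gene, featuretype="CDS"), key=lambda f: (f.start, f.end)
        )
        if not cds:
            continue
        length = sum(f.end - f.start + 1 for f in cds)
        strand = cds[0].strand
        seqid = cds[0].seqid
        contig = genome.get(seqid)
        context = None
        if contig is not None:
            if strand == "-":
                # start codon at the 3'-most CDS coordinate on the + strand;
                # 12-mer window spans 3 nt below to 6 nt above it
                start1 = max(f.end for f in cds)  # 1-based
                lo, hi = start1 - 5, start1 + 6  # 1-based inclusive window
                if lo >= 1 and hi <= len(contig):
                    context = _revcomp(contig[lo - 1 : hi])
            else:
                start1 = min(f.start for f in cds)
                lo, hi = start1 - 6, start1 + 5
                if lo >= 1 and hi <= len(contig):
                    context = contig[lo - 1 : hi]
        if context is not None and not CONTEXT_RE.match(context):
            context = None
        gid = gene.attributes.get("ID", [gene.id])[0]
        rows[gid] = (length, context)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["orf_length_nt", "start_context"]
    )
    table.index.name = "gene_id"
    table["categories"] = [()] * len(table)
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# Analysis configuration


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds for the whole pipeline.

    ti_log2_threshold: differential-translation call threshold (strict >).
    expression_min_tpm: expressed-gene filter on mean TPM (strict >).
    enrichment_alpha: significance level after correction.
    pseudocount: CPM pseudocount added to heavy and light before the ratio.
    replicate_combine: mean of log2 TI across replicates, or pooled CPM sums.
    """

    ti_log2_threshold: float = 0.5
    expression_min_tpm: float = 1.0
    enrichment_alpha: float = 0.001
    correction: str = "bonferroni"
    pseudocount: float = 0.5
    replicate_combine: str = "mean_log2"
    seed: int = 0

    def __post_init__(self):
        if self.ti_log2_threshold < 0 or self.expression_min_tpm < 0:
            raise ParameterError("thresholds must be nonnegative")
        if not (0 < self.enrichment_alpha < 1):
            raise ParameterError("enrichment_alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ParameterError(f"unknown correction: {self.correction}")
        if self.pseudocount < 0:
            raise ParameterError("pseudocount must be >= 0")
        if self.replicate_combine not in ("mean_log2", "pooled_counts"):
            raise ParameterError(
                f"unknown replicate_combine: {self.replicate_combine}"
            )

    @classmethod
    def read(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Write a result table as TSV with 6-significant-digit floats."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
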