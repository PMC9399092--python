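"""Start-codon (Kozak) context frequency matrix and additive scoring.

The context of a start codon is the 6 nucleotides upstream and 3
downstream of the AUG (positions -6..-1 and +4..+6; the A of AUG is +1).
A position frequency matrix is built from the observed contexts — raw
nucleotide incidences, no pseudocounts, no background correction — and a
context is scored as the sum over the 9 variable positions of the matrix
frequency of its nucleotide there. Scores therefore lie in [0, 9]; the
maximum-scoring context is the per-position consensus, because the score
is additive across positions.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContextError, ParameterError
from .io import GeneAnnotation

logger = logging.getLogger(__name__)

BASES = "ACGT"
#: labels of the 9 scored positions relative to the A of AUG (= +1)
POSITIONS = (-6, -5, -4, -3, -2, -1, 4, 5, 6)
_NINE_MER = re.compile(r"^[ACGT]{9}$")
_TWELVE_MER = re.compile(r"^[ACGT]{6}ATG[ACGT]{3}$")


def extract_contexts(annotation: GeneAnnotation) -> list[str]:
    """Collect the 9 variable nucleotides of every valid start context.

    The invariant AUG (12-mer positions 7-9) is removed; genes without a
    valid context are skipped and the number skipped is logged.
    """
    contexts = []
    skipped = 0
    for gene, ctx in annotation.table["start_context"].items():
        if ctx is None or not _TWELVE_MER.match(ctx):
            skipped += 1
            continue
        contexts.append(ctx[:6] + ctx[9:])
    if skipped:
        logger.info("extract_contexts: skipped %d genes without a valid context", skipped)
    return contexts


@dataclass(frozen=True)
class KozakMatrix:
    """9-position x 4-nucleotide frequency matrix of start contexts."""

    frequencies: pd.DataFrame  # index POSITIONS, columns BASES
    n_contexts: int

    def __post_init__(self):
        f = self.frequencies
        if tuple(f.index) != POSITIONS or tuple(f.columns) != tuple(BASES):
            raise ParameterError("matrix must be 9 positions x ACGT")
        if self.n_contexts < 1:
            raise ParameterError("matrix requires >= 1 context")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("each position's frequencies must sum to 1")


def build_matrix(contexts: list[str]) -> KozakMatrix:
    """Nucleotide incidence per position: count(base at p) / n_contexts."""
    if not contexts:
        raise ParameterError("cannot build a frequency matrix from zero contexts")
    for c in contexts:
        if not _NINE_MER.match(c):
            raise ContextError(f"not a valid 9-mer context: {c!r}")
    arr = np.frombuffer("".join(contexts).encode(), dtype="S1").reshape(
        len(contexts), 9
    )
    counts = np.stack(
        [(arr == base.encode()).sum(axis=0) for base in BASES], axis=1
    ).astype(float)
    freq = pd.DataFrame(
        counts / len(contexts), index=list(POSITIONS), columns=list(BASES)
    )
    return KozakMatrix(freq, len(contexts))


def score_context(context: str, matrix: KozakMatrix) -> float:
    """Additive score of a 9-mer context: sum of per-position frequencies."""
    if not _NINE_MER.match(context):
        raise ContextError(f"not a valid 9-mer context: {context!r}")
    f = matrix.frequencies.to_numpy()
    cols = [BASES.index(b) for b in context]
    return float(f[np.arange(9), cols].sum())


def score_annotation(annotation: GeneAnnotation, matrix: KozakMatrix) -> pd.DataFrame:
    """Score every annotated gene with a valid context."""
    rows = []
    for gene, ctx in annotation.table["start_context"].items():
        if ctx is None or not _TWELVE_MER.match(ctx):
            continue
        nine = ctx[:6] + ctx[9:]
        rows.append((gene, nine, score_context(nine, matrix)))
    return pd.DataFrame(rows, columns=["gene_id", "context", "score"]).set_index(
        "gene_id"
    )


def max_scoring_context(matrix: KozakMatrix) -> tuple[str, float, bool]:
    """Per-position consensus, its score, and whether any position is tied.

    Additivity makes the per-position argmax globally optimal. Ties are
    broken alphabetically (A < C < G < T); the returned context is
    rendered with the fixed AUG separator, e.g. ``ACAAAA-AUG-GCU``.
    """
    f = matrix.frequencies.to_numpy()
    best = f.argmax(axis=1)  # argmax takes the first = alphabetically lowest
    score = float(f.max(axis=1).sum())
    tied = bool(((f == f.max(axis=1, keepdims=True)).sum(axis=1) > 1).any())
    nine = "".join(BASES[i] for i in best)
    rna = nine.replace("T", "U")
    rendered = f"{rna[:6]}-AUG-{rna[6:]}"
    return rendered, score, tied
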