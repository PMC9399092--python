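"""Typed errors raised by polyti.

Every validation failure carries enough context (file, line, field) to
locate the offending record; no partially parsed table escapes a reader.
"""


class PolytiError(Exception):
    """Base class for all polyti errors."""


class FormatError(PolytiError):
    """Malformed input file (bad column, non-integer count, bad value)."""

    def __init__(self, message: str, path=None, line=None, field=None):
        parts = [message]
        if path is not None:
            parts.append(f"file={path}")
        if line is not None:
            parts.append(f"line={line}")
        if field is not None:
            parts.append(f"field={field}")
        super().__init__(" | ".join(str(p) for p in parts))
        self.path, self.line, self.field = path, line, field


class ManifestError(PolytiError):
    """Sample manifest invalid, or counts columns disagree with it."""


class ContextError(PolytiError):
    """Start-codon context does not match [ACGT]{6}ATG[ACGT]{3} / [ACGT]{9}."""


class PairingError(PolytiError):
    """A (strain, condition) group lacks a matched heavy or light fraction."""


class ParameterError(PolytiError):
    """Invalid analysis or generator parameter."""


class AlignmentError(PolytiError):
    """Two tables that must share a gene universe do not."""


class NormalizationError(PolytiError):
    """Normalization impossible (e.g. an all-zero sample column)."""


class MeasurementMissingError(PolytiError):
    """A required (sample, gene) qPCR well or peptide row is absent."""
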