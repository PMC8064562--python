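"""Exception types shared across the toolkit."""


class HalobarcodeError(Exception):
    """Base class for all package errors."""


class FastaParseError(HalobarcodeError):
    """Malformed FASTA entry (bad header grammar or structure)."""


class AlphabetError(HalobarcodeError):
    """Sequence contains characters outside the IUPAC nucleotide alphabet."""


class DomainError(HalobarcodeError):
    """Numeric argument outside the operation's domain."""


class SaturationError(HalobarcodeError):
    """Distance-model correction undefined (substitution saturation)."""

    def __init__(self, message, pairs=None):
        super().__init__(message)
        self.pairs = list(pairs) if pairs else []


class SchemaError(HalobarcodeError):
    """Tabular input is missing required columns or has out-of-range fields."""


class GridFormatError(HalobarcodeError):
    """ESRI ASCII grid header/value mismatch."""


class PipelineError(HalobarcodeError):
    """Pipeline stage misconfiguration or missing inputs; names the producer stage."""
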