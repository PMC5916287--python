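"""Exception hierarchy for the circinfer pipeline."""


class CircinferError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CircinferError):
    """A file does not conform to its declared format."""


class PairingError(FormatError):
    """Paired FASTQ files disagree on record counts."""


class MissingReferenceError(CircinferError):
    """The requested reference id is absent from a SAM header."""


class NoCircularityCandidate(CircinferError):
    """No duplicated k-mer pair satisfies the minimum span.

    Carries ``largest_span`` (the widest duplicated-k-mer span observed,
    or None if no duplicate exists at all) to help the user pick a
    smaller ``min_span`` or a different k.
    """

    def __init__(self, message: str, largest_span: int | None = None):
        super().__init__(message)
        self.largest_span = largest_span


class DegenerateInputError(CircinferError):
    """Input too short or otherwise degenerate for the operation."""


class ConfigurationError(CircinferError):
    """Mutually inconsistent parameters."""


class ConsistencyError(CircinferError):
    """Alignments and reference disagree (e.g. out-of-bounds interval)."""


class UndefinedMetricError(CircinferError):
    """A metric is undefined for the given input (e.g. no mapped reads)."""
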