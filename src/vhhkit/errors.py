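"""Exception and warning types used across vhhkit."""


class VhhkitError(Exception):
    """Base class for all vhhkit errors."""


class UnnumberableSequence(VhhkitError):
    """Raised when a sequence cannot be placed on the IMGT 1-128 scaffold."""


class FormatError(VhhkitError):
    """Raised for malformed numbering tables or FASTA input."""


class UnknownRegion(VhhkitError):
    """Raised when a region name is not one of fr1-fr4 / cdr1-cdr3."""


class MissingPosition(VhhkitError):
    """Raised when a required IMGT position is absent from a sequence."""


class EmptyInput(VhhkitError):
    """Raised when an operation receives no sequences."""


class InvalidDistribution(VhhkitError):
    """Raised when a probability vector does not sum to one."""


class DegenerateMatrix(VhhkitError):
    """Raised when a coupling matrix is too small to cluster."""


class UnknownMotif(VhhkitError):
    """Raised when a Hallmark motif string contains non-amino-acid characters."""


class EmptySubset(VhhkitError):
    """Raised when statistics are requested for an empty subset."""


class NoHumanGermline(VhhkitError):
    """Raised when the germline database contains no human entry."""


class IncompatibleScaffold(VhhkitError):
    """Raised when a germline lacks positions required for grafting."""


class ParseError(VhhkitError):
    """Raised for malformed affinity tables; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DuplicateVariantId(VhhkitError):
    """Raised when two variants share an identifier."""


class ConfigError(VhhkitError):
    """Raised for invalid generator or run configuration."""


class CapExceededWarning(UserWarning):
    """Emitted when combinatorial variant enumeration is truncated at the cap."""
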