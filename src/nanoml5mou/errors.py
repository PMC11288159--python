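"""Exception hierarchy shared across the package."""


class NanomlError(Exception):
    """Base class for all package-specific errors."""


class EventTableFormatError(NanomlError):
    """The event table header does not match the canonical schema."""


class EventTableParseError(NanomlError):
    """A row of an event table violates the record invariants."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateEventError(NanomlError):
    """Two events claim the same (read_id, ref_name, ref_pos)."""


class CoordinateError(NanomlError):
    """Event positions fall outside the reference sequence."""


class LabellingError(NanomlError):
    """An operation requiring modified/unmodified labels got unlabelled or single-class data."""


class SchemaError(NanomlError):
    """Feature columns or k-mer identity do not match what a model was fitted on."""


class InsufficientDataError(NanomlError):
    """A k-mer dataset is too small to train a cross-validated model."""


class SamplingError(NanomlError):
    """A read pool cannot supply the requested number of reads."""


class EstimateError(NanomlError):
    """A stoichiometry estimate was requested from an empty profile."""


class UsageError(NanomlError):
    """Invalid arguments to a library operation (unknown scheme, empty model map, ...)."""


class ConfigError(NanomlError):
    """A pipeline run configuration failed validation."""
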