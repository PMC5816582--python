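"""Exception hierarchy shared across the pipeline."""


class HetArrayError(Exception):
    """Base class for all package errors."""


class FormatError(HetArrayError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(HetArrayError):
    """Well-formed input that violates a semantic contract."""


class DesignError(ValidationError):
    """Experiment design table is inconsistent (arrays, dyes, pairing)."""


class ModelError(HetArrayError):
    """A statistical model cannot be fitted on the given data."""
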