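"""Exception hierarchy shared across the package."""


class TwinEpiError(Exception):
    """Base class for all package errors."""


class FormatError(TwinEpiError):
    """Malformed input: missing columns, illegal characters, bad schema."""


class ValidationError(TwinEpiError):
    """Well-formed input violating a cohort invariant."""


class ParameterError(TwinEpiError):
    """A parameter outside its documented domain."""


class InsufficientDataError(TwinEpiError):
    """Too few observations for the requested statistic."""
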