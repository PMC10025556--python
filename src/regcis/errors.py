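"""Exception hierarchy shared across the pipeline."""


class RegcisError(Exception):
    """Base class for all package errors."""


class FormatError(RegcisError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(RegcisError):
    """Parsed data violates a domain invariant (e.g. read_count < 1)."""


class ParameterError(RegcisError):
    """A parameter is outside its admissible range or inconsistent."""


class AnalysisError(RegcisError):
    """A computation cannot proceed (empty input, undefined quantity)."""
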