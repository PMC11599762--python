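"""Package-wide exception types."""


class HobrainError(Exception):
    """Base class for all package errors."""


class DegenerateSignalError(HobrainError, ValueError):
    """A signal (or derived series) has zero variance where variance is required."""


class DimensionError(HobrainError, ValueError):
    """Inputs have incompatible shapes or sizes."""


class ParseError(HobrainError, ValueError):
    """A text input file could not be parsed."""
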