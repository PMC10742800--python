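"""Exception hierarchy for pairturn."""


class PairturnError(Exception):
    """Base class for all pairturn errors."""


class FormatError(PairturnError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class DataError(PairturnError):
    """Well-formed file with invalid content (NaNs, non-monotone frames, >2 fish)."""


class ConfigError(PairturnError):
    """Invalid configuration values."""


class TooShortError(PairturnError):
    """A series is shorter than the operation requires."""


class UndefinedAngleError(PairturnError):
    """An angle is requested for a degenerate geometry (zero-length vector)."""


class ConvergenceError(PairturnError):
    """An iterative solver failed to converge within its iteration budget."""
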