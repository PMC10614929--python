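"""Exception types shared across the package."""


class GuvmemError(Exception):
    """Base class for all package errors."""


class FormatError(GuvmemError):
    """A file does not conform to the expected external format."""


class ParameterError(GuvmemError):
    """An argument violates a documented precondition."""


class NoForegroundError(GuvmemError):
    """A constant crop offers no foreground/background separation."""


class GridMismatchError(GuvmemError):
    """Replicate time series are not on a common time grid."""
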