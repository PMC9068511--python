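"""Exception types shared across the package."""


class IsoretainError(Exception):
    """Base class for all package-specific errors."""


class SafFormatError(IsoretainError):
    """A SAF annotation file could not be parsed."""


class UndefinedRateError(IsoretainError):
    """A retention rate is undefined because the CDS has zero reads."""


class InvalidPairingError(IsoretainError):
    """Treated/control records do not refer to the same feature."""


class EmptyDistributionError(IsoretainError):
    """A single-cell distribution has no usable values."""


class InsufficientDataError(IsoretainError):
    """Too few data points inside the requested fitting window."""


class InvalidReferenceError(IsoretainError):
    """A reference growth rate is non-positive."""


class ExtrapolationError(IsoretainError):
    """The requested inhibition level lies outside the measured range."""


class InvalidTableError(IsoretainError):
    """A survival table violates its schema (e.g. a missing population)."""
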