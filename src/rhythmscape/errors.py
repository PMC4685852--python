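"""Exception hierarchy for rhythmscape."""


class RhythmscapeError(Exception):
    """Base class for all package errors."""


class FormatError(RhythmscapeError):
    """A note table is malformed (missing mandatory columns, etc.)."""


class EmptyDatasetError(RhythmscapeError):
    """No usable rows / no feature values in the input."""


class ParameterError(RhythmscapeError):
    """An operation parameter violates its precondition."""


class SmoothingError(RhythmscapeError):
    """Kernel density estimate undefined (fewer than two samples)."""


class EmptyWindowError(RhythmscapeError):
    """A within-day clock window contains no intervals."""


class FitError(RhythmscapeError):
    """Curve fit undefined for the given points."""


class ConfigError(RhythmscapeError):
    """Invalid simulation or run configuration."""
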