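"""Exception hierarchy.

Everything user-facing derives from :class:`PhasorLabError` so callers can
catch the library broadly; validation-type failures also derive from
``ValueError`` to play well with generic input checking.
"""


class PhasorLabError(Exception):
    """Base class for all phasorlab errors."""


class ValidationError(PhasorLabError, ValueError):
    """Invalid argument values or inconsistent array shapes."""


class FormatError(PhasorLabError, ValueError):
    """An on-disk artifact does not match the expected layout."""


class MetadataError(PhasorLabError, ValueError):
    """Required acquisition metadata (frequency / spectral band) is missing."""


class AliasingError(ValidationError):
    """Requested harmonic is too high for the number of bins."""


class DegenerateReferenceError(PhasorLabError, ValueError):
    """Calibration reference has zero modulation at some harmonic."""


class ConditioningError(PhasorLabError, ValueError):
    """Unmixing system is numerically singular (e.g. duplicate components)."""


class ColorTableError(PhasorLabError, KeyError):
    """A label present in a label image has no assigned color."""


class CalibrationWarning(UserWarning):
    """Emitted when lifetime projections run on an uncalibrated field."""
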