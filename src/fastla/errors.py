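"""Exception hierarchy for fastla.

Every error raised by the library derives from :class:`FastLAError` so that
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class FastLAError(Exception):
    """Base class for all fastla errors."""


class FormatError(FastLAError):
    """Unreadable, mixed or unsupported file content."""


class CalibrationError(FastLAError):
    """Missing or invalid physical calibration (pixel spacing, frame timing)."""


class DegenerateSeriesError(FastLAError):
    """A cine series too short or too small to analyse."""


class ValidationError(FastLAError):
    """Invalid landmark annotations or configuration values."""


class FlatTextureError(FastLAError):
    """A template (mask) with zero intensity variance cannot be matched."""


class TrackingError(FastLAError):
    """Tracking aborted; the message carries the frame and landmark context."""


class MonophasicCurveError(FastLAError):
    """Strain curve lacks the two diastolic strain-rate lobes (no atrial kick)."""


class DomainError(FastLAError):
    """Numerical input outside the mathematical domain of a formula."""
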