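"""Exception hierarchy shared across the package."""


class StrabiscreenError(Exception):
    """Base class for all package-specific errors."""


class ApertureError(StrabiscreenError, ValueError):
    """A pupil centre was placed outside the visible eyelid aperture."""


class ConfigError(StrabiscreenError, ValueError):
    """An invalid training or run configuration value."""


class DetectorError(StrabiscreenError, RuntimeError):
    """The eye detector adapter itself failed (distinct from 'no face found')."""


class FilterError(StrabiscreenError, ValueError):
    """An eye pair that never passed the size-ratio filter reached a stage
    that requires filtered input."""


class TrainingDivergedError(StrabiscreenError, RuntimeError):
    """Training produced a non-finite loss."""


class SizeMismatchError(StrabiscreenError, ValueError):
    """Image size does not match the model input size, or calibration and
    screening were run at different input sizes."""


class AnnotationError(StrabiscreenError, ValueError):
    """Malformed or unreadable annotation input."""


class UnscreenableError(StrabiscreenError, RuntimeError):
    """No frame of a video survived the size filter."""
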