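"""Exception and warning types shared across the package."""


class OCE4DError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OCE4DError, ValueError):
    """A configuration object violates its invariants."""


class DataError(OCE4DError, ValueError):
    """Input data is malformed (non-finite values, wrong dtype, ...)."""


class ShapeError(OCE4DError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class CropError(OCE4DError, ValueError):
    """A requested crop does not fit inside the available extent."""


class SurfaceDetectionError(OCE4DError, ValueError):
    """The phantom surface could not be located in an intensity volume."""


class SchemaError(OCE4DError, KeyError):
    """A persisted dataset is missing required keys or attributes."""


class UnreliableEstimateError(OCE4DError, RuntimeError):
    """A time-of-flight estimate failed its quality or sign checks."""


class TrainingDivergedError(OCE4DError, RuntimeError):
    """The training loss became non-finite."""


class ClampedRangeWarning(UserWarning):
    """A derived quantity fell outside its physical range and was clamped."""
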