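"""Exception hierarchy shared across the package."""


class PalaeocoastError(Exception):
    """Base class for all package-specific errors."""


class CurveFormatError(PalaeocoastError, ValueError):
    """A calibration-curve file could not be parsed."""


class CurveRangeError(PalaeocoastError, ValueError):
    """A calendar age falls outside the span of the calibration curve."""


class CalibrationError(PalaeocoastError, RuntimeError):
    """A determination is inconsistent with the curve everywhere."""


class ValidationError(PalaeocoastError, ValueError):
    """Structural validation of a domain object failed."""


class GridMismatchError(PalaeocoastError, ValueError):
    """Two gridded series do not share the same calendar grid."""


class DegenerateComponentError(PalaeocoastError, RuntimeError):
    """A WA-PLS component has (numerically) zero variance."""

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(message or f"degenerate WA-PLS component {component}: "
                         "sample scores have zero variance")


class PredictionError(PalaeocoastError, ValueError):
    """A fossil assemblage cannot be scored by a fitted model."""


class StandardizationError(PalaeocoastError, ValueError):
    """A proxy series cannot be z-standardized (zero variance)."""


class ConfigurationError(PalaeocoastError, ValueError):
    """Missing or inconsistent run configuration."""


class ParameterError(PalaeocoastError, ValueError):
    """Invalid parameters passed to a synthetic-data generator."""
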