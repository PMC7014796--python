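"""Exception hierarchy for the carrgo package."""


class CarrgoError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CarrgoError, ValueError):
    """Inputs violate a documented precondition (non-finite, wrong sign, ...)."""


class IntegrationError(CarrgoError, RuntimeError):
    """The ODE solver failed to advance the solution.

    Attributes
    ----------
    last_valid_time : float or None
        Last time point the integrator reached before failing.
    """

    def __init__(self, message, last_valid_time=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class DegenerateScalingError(CarrgoError, ValueError):
    """Nondimensionalization is undefined (rho = 0)."""


class UndefinedRatioError(CarrgoError, ZeroDivisionError):
    """Endpoint cancer-cell/T-cell ratio undefined because Y(t_end) ~ 0."""


class InvalidPointError(CarrgoError, ValueError):
    """A point handed to the stability classifier is not an equilibrium."""


class PlateFormatError(CarrgoError, ValueError):
    """A plate CSV violates the expected dialect (e.g. non-monotone time)."""


class MetadataError(CarrgoError, KeyError):
    """Well metadata missing or inconsistent."""


class PreprocessingError(CarrgoError, ValueError):
    """Fit-window selection produced an empty or invalid window."""


class CalibrationError(CarrgoError, ValueError):
    """Cell-index/cell-count calibration is invalid (slope <= 0)."""


class InvalidIntervalError(CarrgoError, ValueError):
    """Down-sampling interval shorter than the native sampling interval."""


class DegenerateDataError(CarrgoError, ValueError):
    """Series carries no usable signal for fitting (e.g. constant)."""


class UndefinedR2Error(CarrgoError, ValueError):
    """R^2 undefined because one of the vectors has zero variance."""


class InsufficientDataError(CarrgoError, ValueError):
    """Too few observations / groups for the requested statistic."""


class UnderDeterminedError(CarrgoError, ValueError):
    """Fewer observations than free parameters."""


class ConfigError(CarrgoError, ValueError):
    """Invalid run or plate configuration."""
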