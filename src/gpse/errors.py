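"""Exception hierarchy for the gpse package."""


class GPSEError(Exception):
    """Base class for all package errors."""


class InvalidMatrixError(GPSEError, ValueError):
    """A Mueller matrix violates a precondition (e.g. m11 <= 0)."""


class InvalidStateError(GPSEError, ValueError):
    """A Stokes vector violates a precondition (e.g. s0 <= 0)."""


class ParameterError(GPSEError, ValueError):
    """An operation parameter is out of its valid range."""


class ProjectionError(GPSEError, ValueError):
    """Poincare projection failed (non-positive output intensity)."""


class InsufficientDataError(GPSEError, ValueError):
    """Too few points/frames for the requested fit or inversion."""


class FitError(GPSEError, RuntimeError):
    """Quadric fit did not yield an ellipsoid."""


class ConfigurationError(GPSEError, ValueError):
    """A measurement configuration is unusable (aliasing, rank deficiency)."""


class FormatError(GPSEError, ValueError):
    """A file does not conform to the expected on-disk format."""


class AmbiguousUnwrapError(GPSEError, RuntimeError):
    """Dual-wavelength unwrapping found no consistent candidate."""

    def __init__(self, message, candidates=None):
        super().__init__(message)
        self.candidates = candidates or []
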