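"""Exception and warning types shared across the package."""


class H2O2PermError(Exception):
    """Base class for all errors raised by this package."""


class InconsistentMeasurementError(H2O2PermError, ValueError):
    """Measured concentrations violate the mass-balance preconditions."""


class GeometryError(H2O2PermError, ValueError):
    """Vesicle/cell geometry is invalid (non-positive dimensions)."""


class InsufficientDataError(H2O2PermError, ValueError):
    """Too few points to perform the requested regression."""


class NoLatencyError(H2O2PermError, ValueError):
    """Latency ratio outside (0, 1): the membrane shows no permeability barrier."""


class FitError(H2O2PermError, RuntimeError):
    """Nonlinear fit failed to converge after bounded restarts."""


class IntegrationError(H2O2PermError, RuntimeError):
    """ODE integration failed or produced unphysical output."""


class NoLatencyWarning(UserWarning):
    """Flag (batch mode) that intact and disrupted activities coincide (R >= 1)."""
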