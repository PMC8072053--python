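"""Exception hierarchy."""


class ChromoCGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChromoCGError):
    """Invalid run configuration (bad range, step, missing field ...)."""


class DomainError(ChromoCGError):
    """A value lies outside the valid domain of a reference landscape or model."""


class InvalidReferenceError(ChromoCGError):
    """A reference free-energy landscape evaluates to a non-finite value."""


class DegenerateGeometryError(ChromoCGError):
    """Point cloud too degenerate for the requested geometric operation."""


class SelectionError(ChromoCGError):
    """An atom selection matched nothing or could not be interpreted."""


class ConvergenceError(ChromoCGError):
    """An iterative solver failed to converge; carries the best iterate."""

    def __init__(self, message, result=None, residual=None):
        super().__init__(message)
        self.result = result
        self.residual = residual


class FitDomainError(ChromoCGError):
    """The fit window does not satisfy the preconditions of the fit."""


class EmptyAnalysisError(ChromoCGError):
    """No usable samples remain for the requested analysis."""
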