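"""Exception hierarchy used across polyflux."""


class PolyfluxError(Exception):
    """Base class for all polyflux errors."""


class ValidationError(PolyfluxError):
    """Input violates a documented invariant (bad bounds, duplicate ids, ...)."""


class ModelParseError(PolyfluxError):
    """A model file could not be parsed in the requested format."""

    def __init__(self, fmt: str, message: str):
        self.format = fmt
        super().__init__(f"[{fmt}] {message}")


class InfeasibleModelError(PolyfluxError):
    """The steady-state set {S v = 0, lb <= v <= ub} is empty.

    Carries the LP solver's status message as a certificate of infeasibility.
    """

    def __init__(self, message: str, certificate: str | None = None):
        self.certificate = certificate
        super().__init__(message)


class BoundednessError(PolyfluxError):
    """A direction of unbounded recession was found where none is allowed."""


class NotFullDimensionalError(PolyfluxError):
    """The polytope has Chebyshev radius below tolerance (flat body)."""


class DegenerateSeriesError(PolyfluxError):
    """A diagnostic was asked of a constant (zero-variance) series."""


class GeometryError(PolyfluxError):
    """Numerical geometry failure, e.g. a billiard trajectory escaping the body."""


class ConvergenceError(PolyfluxError):
    """An iterative procedure hit its cap before meeting its gates.

    ``payload`` carries whatever partial state is useful for post-mortem
    (last condition number, partial diagnostics report, ...).
    """

    def __init__(self, message: str, payload=None):
        self.payload = payload
        super().__init__(message)
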