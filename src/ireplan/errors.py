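"""Exception hierarchy for planning, solving and inversion failures."""


class IREPlanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IREPlanError):
    """A requested geometry/electrode/plan combination is unsupported."""


class PlacementError(ConfigurationError):
    """An electrode would fall outside the domain or overlap another."""


class DomainError(IREPlanError, ValueError):
    """An argument is outside its physically meaningful range."""


class FormatError(IREPlanError, ValueError):
    """An input file or array does not have the expected form."""


class EmptyInputError(IREPlanError, ValueError):
    """A non-empty collection, mask or region was required."""


class ConvergenceError(IREPlanError):
    """The nonlinear field solve did not converge.

    Carries the residual at termination so callers can diagnose whether
    the iteration was close or diverging.
    """

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class DegenerateSolutionError(IREPlanError):
    """A derived quantity (e.g. resistance) is undefined for this solution."""


class OutOfRangeError(IREPlanError, ValueError):
    """A measured value lies outside the range spanned by the simulation."""
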