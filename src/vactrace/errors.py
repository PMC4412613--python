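"""Exception hierarchy for vactrace."""


class VactraceError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VactraceError, ValueError):
    """Malformed or physically impossible input (negative concentration, ...)."""


class UndefinedPotentialError(VactraceError, ValueError):
    """Equilibrium potential is undefined (zero concentration on one side)."""


class ConfigurationError(VactraceError, ValueError):
    """Missing configuration, e.g. an ion without a tabulated mobility."""


class NoSolutionError(VactraceError, RuntimeError):
    """A root search found no solution in its bracket."""


class ConvergenceError(VactraceError, RuntimeError):
    """Iterative solver failed to converge; carries residual information."""

    def __init__(self, message, residuals=None, partial=None):
        super().__init__(message)
        self.residuals = residuals
        self.partial = partial


class ProtocolError(VactraceError, ValueError):
    """Invalid voltage-step protocol definition."""


class NoReversalError(VactraceError, RuntimeError):
    """I/V curve does not cross zero current."""
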