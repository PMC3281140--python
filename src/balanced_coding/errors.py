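"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter is outside its valid domain (non-finite field, beta <= 0, ...)."""


class EnumerationSizeError(ValueError):
    """The system is too large for exact 2**n enumeration under the configured cap."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge where a converged result is required."""


class NoRootError(RuntimeError):
    """Root finding failed: no sign change in the (possibly expanded) bracket."""


class UndefinedStatisticError(ZeroDivisionError):
    """A ratio statistic (Fano factor, Poisson-form Fisher information) has a zero
    or negative denominator and is undefined."""


class SimulationError(RuntimeError):
    """Numerical failure inside the spiking simulator (voltage out of bounds)."""
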