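"""Exception hierarchy shared across the package."""


class JmassocError(Exception):
    """Base class for all package errors."""


class ConfigurationError(JmassocError):
    """Invalid model/spec configuration (knots, structure/parameter mismatch...)."""


class DomainError(JmassocError):
    """An argument lies outside the mathematical domain of an operation."""


class DataError(JmassocError):
    """Input data violate a dataset invariant."""


class SimulationError(JmassocError):
    """A stochastic simulation step failed (e.g. root-finder non-convergence)."""


class InitializationError(JmassocError):
    """Sampler could not be started from a finite posterior state."""
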