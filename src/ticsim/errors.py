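"""Exception hierarchy shared across the package."""


class TicsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TicsimError, ValueError):
    """A configuration object holds an invalid field value."""


class DomainError(TicsimError, ValueError):
    """An argument is outside the domain an operation is defined on."""


class EstimationError(TicsimError, RuntimeError):
    """Model estimation cannot proceed (bad inputs, separation, rank loss)."""


class SimulationError(TicsimError, RuntimeError):
    """A Monte Carlo step could not be carried out for a person/wave."""


class ImputationError(TicsimError, RuntimeError):
    """Multiple imputation cannot proceed on the given panel."""
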