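"""Package-wide exception types."""


class AfpomError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AfpomError):
    """An unknown name, missing preset, or inconsistent configuration."""


class ValidationError(AfpomError, ValueError):
    """An input violates a documented precondition or invariant."""


class SimulationError(AfpomError, RuntimeError):
    """Numerical failure during integration (non-finite state)."""
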