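"""Exception types shared across the package."""


class ReachRLError(Exception):
    """Base class for all package-specific errors."""


class InvalidMultiplierError(ReachRLError, ValueError):
    """Noise multiplier alpha below 1 (the no-noise floor)."""


class InsufficientDataError(ReachRLError, ValueError):
    """Too few trials/angles to compute the requested quantity."""


class ConfigurationError(ReachRLError, ValueError):
    """Invalid protocol, agent, or run configuration."""


class DegenerateModelError(ReachRLError, ValueError):
    """Model with zero total variance in some reward context."""


class OraclePreconditionError(ReachRLError, ValueError):
    """Closed-form likelihood requested for a model it does not cover."""


class ContractError(ReachRLError, ValueError):
    """Caller violated an interface contract (unbalanced fits, bad weights, ...)."""


class EmptySelectionError(ReachRLError, ValueError):
    """A trial filter selected nothing."""


class DataError(ReachRLError, ValueError):
    """Non-finite or otherwise unusable observations."""
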