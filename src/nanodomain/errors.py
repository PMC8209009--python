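"""Exception hierarchy shared across the package."""


class NanodomainError(Exception):
    """Base class for all package-specific errors."""


class StructuralError(NanodomainError):
    """Inputs have inconsistent shapes, sizes, or missing columns."""


class SchemaError(NanodomainError):
    """A declared atom, column, or species could not be resolved."""


class InvalidReferenceError(NanodomainError):
    """The isotropic reference for G-factor estimation is unusable."""


class BinningError(NanodomainError):
    """Too few valid pixels (or points) to form the requested bins."""


class SimulationError(NanodomainError):
    """A synthetic-data request is inconsistent or would run away."""


class ConfigError(NanodomainError):
    """Pipeline configuration failed strict validation."""
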