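"""Exception hierarchy used across the package."""


class RaftdynError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RaftdynError, ValueError):
    """Invalid configuration or precondition violation."""


class PackingError(RaftdynError, RuntimeError):
    """Domain placement failed: requested density is infeasible."""


class MemoryGuardError(RaftdynError, RuntimeError):
    """Requested ensemble would exceed the in-memory size cap."""


class DegenerateTraceError(RaftdynError, ValueError):
    """Autocorrelation of a constant (zero-variance) trace is undefined."""


class DegenerateNormalizationError(RaftdynError, ValueError):
    """FRAP normalization is undefined when no bleach occurred."""


class UnderdeterminedFitError(RaftdynError, ValueError):
    """Fewer data points than free model parameters."""


class UnphysicalLawError(RaftdynError, ValueError):
    """Diffusion-law slope is non-positive; D_eff is undefined."""


class UnknownConditionError(RaftdynError, KeyError):
    """Condition name is not a known experimental preset."""
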