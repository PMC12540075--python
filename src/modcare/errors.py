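"""Exception types shared across the package."""


class ModcareError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(ModcareError):
    """Raised when a configuration object violates its invariants."""


class DomainError(ModcareError):
    """Raised when an operation receives input outside its domain."""
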