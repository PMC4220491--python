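"""Exception types shared across the package."""


class RiceNetError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(RiceNetError):
    """An invalid configuration value or combination (names the violated invariant)."""


class DataError(RiceNetError):
    """Input data violate a precondition (degenerate blocks, mismatched axes, ...)."""
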