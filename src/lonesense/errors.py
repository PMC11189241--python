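"""Exception types shared across the package."""


class LonesenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LonesenseError):
    """A configuration value is invalid. The message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field '{field}': {message}")


class DataError(LonesenseError):
    """Input data violate a precondition (e.g. no night-time GPS fixes)."""
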