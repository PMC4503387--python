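"""Exception hierarchy shared across mpquant modules."""


class MPQError(Exception):
    """Base class for all mpquant errors."""


class ConfigurationError(MPQError):
    """An invalid configuration value; ``field`` names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class NyquistError(ConfigurationError):
    """Beat frequency at or above half the frame rate cannot be sampled."""


class InsufficientDataError(MPQError):
    """Too few samples for the requested computation."""


class SamplingError(MPQError):
    """Track timestamps are not uniformly spaced."""
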