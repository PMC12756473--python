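"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when a user-supplied configuration value is invalid."""


class FormatError(ValueError):
    """Raised when an epoch container file is malformed or unreadable."""
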