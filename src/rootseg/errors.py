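"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration field value."""


class ShapeError(ValueError):
    """An input whose shape violates an operation's contract."""


class DataError(ValueError):
    """Malformed annotation or mask data."""
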