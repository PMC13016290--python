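"""Package-level exception types."""


class ConfigError(ValueError):
    """Raised when an architecture or run configuration is inconsistent."""


class ShapeError(ValueError):
    """Raised when array shapes violate an operation's contract."""
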