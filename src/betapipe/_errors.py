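"""Shared exception types."""


class ConfigError(ValueError):
    """Invalid or infeasible configuration."""


class DataError(ValueError):
    """Malformed or out-of-contract data."""


class FitError(RuntimeError):
    """Model fit failed (singular or degenerate)."""
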