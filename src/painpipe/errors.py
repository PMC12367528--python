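"""Exception hierarchy shared across the pipeline stages."""


class PainpipeError(Exception):
    """Base class for all pipeline failures."""


class ConfigError(PainpipeError):
    """Invalid or inconsistent configuration."""


class DataError(PainpipeError):
    """Malformed, contradictory or degenerate input data."""


class NumericalError(PainpipeError):
    """A numerical procedure failed (non-convergence, separation, ...)."""
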