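"""Exception types shared across the pipeline."""


class PPGHTError(Exception):
    """Base class for all pipeline errors."""


class DegenerateSignalError(PPGHTError):
    """Raised when a statistic is undefined for the input (e.g. constant signal)."""


class ConfigError(PPGHTError):
    """Raised for invalid or contradictory run configuration."""


class DataFormatError(PPGHTError):
    """Raised when input files cannot be parsed into records/tables."""
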