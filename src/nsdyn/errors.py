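"""Exception hierarchy shared across pipeline stages."""


class NsdynError(Exception):
    """Base class for all package errors."""


class ConfigError(NsdynError, ValueError):
    """Invalid or unknown configuration value (CLI exit code 2)."""


class DataFormatError(NsdynError, ValueError):
    """Malformed input data or file (CLI exit code 3)."""


class StageError(NsdynError, RuntimeError):
    """A pipeline stage failed after valid configuration (exit code 4)."""
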