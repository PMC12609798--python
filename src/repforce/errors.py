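"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, InputError -> 3,
NumericalError -> 4, anything else -> 1.
"""


class RepforceError(Exception):
    """Base class for all package errors."""


class ConfigError(RepforceError):
    """Invalid configuration or parameter values."""


class InputError(RepforceError):
    """Invalid or inconsistent input data."""


class NumericalError(RepforceError):
    """A computation could not be carried out (degenerate data, etc.)."""
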