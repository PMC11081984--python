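"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
validation/configuration errors -> 2, computation errors -> 3, I/O -> 4.
"""


class LcqError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(LcqError):
    """Invalid configuration or precondition violation detected before compute."""

    exit_code = 2


class SchemaError(ConfigError):
    """Malformed input file (wrong header, unparseable rows, empty table)."""


class PlacementError(ConfigError):
    """Simulated structures cannot be placed within the requested field."""


class ComputationError(LcqError):
    """A statistic is undefined or a numerical stage failed on valid-looking input."""

    exit_code = 3


class PipelineError(LcqError):
    """A pipeline stage failed; carries the stage name and the propagated cause."""

    exit_code = 3

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
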