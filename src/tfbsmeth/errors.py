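"""Exception hierarchy.

ConfigurationError: invalid parameters or configuration files.
FormatError: malformed on-disk input (readers reject rather than coerce).
DataError: structurally valid input that violates analysis preconditions.
StageError: a pipeline stage failed; carries the stage name.
"""


class TfbsMethError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TfbsMethError):
    pass


class FormatError(TfbsMethError):
    pass


class DataError(TfbsMethError):
    pass


class StageError(TfbsMethError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
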