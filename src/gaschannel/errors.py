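"""Exception hierarchy.

All package-specific failures derive from :class:`GasChannelError` so callers
can catch one base class.  ``InputError`` marks problems with user-supplied
files or configuration; ``AnalysisError`` marks violated preconditions inside
an analysis; ``StageError`` wraps a pipeline stage failure with its stage name.
"""


class GasChannelError(Exception):
    """Base class for all errors raised by gaschannel."""


class InputError(GasChannelError):
    """An input file, record or configuration value is missing or malformed."""


class AnalysisError(GasChannelError):
    """A precondition of an analysis operation is violated."""


class StageError(GasChannelError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
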