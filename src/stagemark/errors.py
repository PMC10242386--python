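"""Exception hierarchy.

The CLI maps these onto distinct exit codes (parse 2, configuration 3,
pipeline stage 4) so batch callers can tell malformed inputs apart from
bad settings and from analysis failures.
"""


class StagemarkError(Exception):
    """Base class for all package errors."""


class ParseError(StagemarkError):
    """Malformed input file (ragged rows, duplicate ids, non-numeric cells)."""


class ConfigurationError(StagemarkError):
    """Invalid parameter or an input that violates an operation's contract."""


class StageError(StagemarkError):
    """Failure inside a named pipeline stage; wraps the original error."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
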