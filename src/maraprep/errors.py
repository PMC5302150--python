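"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`MaraprepError`
so the CLI can map error classes onto exit codes (config=2, processing=3,
submission=4).
"""


class MaraprepError(Exception):
    """Base class for all errors raised by maraprep."""

    exit_code = 1


class ParseError(MaraprepError):
    """A malformed input file; the message names the file and line number."""

    exit_code = 3

    def __init__(self, message: str, path=None, line: int | None = None):
        if path is not None and line is not None:
            message = f"{path}:{line}: {message}"
        elif path is not None:
            message = f"{path}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class ValidationError(MaraprepError):
    """Input parsed but violates a domain invariant."""

    exit_code = 3


class ConfigError(MaraprepError):
    """Invalid job configuration (data type, assembly, missing inputs)."""

    exit_code = 2


class ProcessingError(MaraprepError):
    """A pipeline stage failed on otherwise valid input."""

    exit_code = 3


class EstimationError(ProcessingError):
    """A statistical estimate is undefined for the given data."""


class SubmissionError(MaraprepError):
    """Upload to the analysis server failed."""

    exit_code = 4
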