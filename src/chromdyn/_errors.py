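"""Exception hierarchy shared across the pipeline."""


class ChromdynError(Exception):
    """Base class for all chromdyn errors."""


class ArgumentError(ChromdynError, ValueError):
    """A parameter violates a documented precondition."""


class CapacityError(ChromdynError):
    """The genome is too small to place the requested elements."""


class ParseError(ChromdynError, ValueError):
    """A malformed input record; message names the offending line."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
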