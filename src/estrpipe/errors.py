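"""Exception types shared across the pipeline."""


class EstrPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(EstrPipeError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(EstrPipeError, ValueError):
    """A malformed input file; carries the 1-based line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DataError(EstrPipeError, ValueError):
    """Inconsistent data handed to an analysis step (duplicates, empty strata...)."""
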