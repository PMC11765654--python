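"""Exception hierarchy shared across the pipeline."""


class CanopymedError(Exception):
    """Base class for all package errors."""


class ParseError(CanopymedError):
    """A tabular input could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(CanopymedError):
    """Input parsed but violated a domain invariant."""


class ModelSpecError(CanopymedError):
    """A model block could not be assembled from the given inputs."""


class ConvergenceError(CanopymedError):
    """A posterior failed the convergence gate and the caller did not force."""
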