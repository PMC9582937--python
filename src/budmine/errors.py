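"""Exception hierarchy shared across the package.

Validation problems (bad user input, malformed files, out-of-range
thresholds) raise :class:`ValidationError` subclasses so the command-line
layer can map them to exit code 2, while unexpected stage failures
propagate as :class:`StageError` (exit code 3).
"""


class BudmineError(Exception):
    """Base class for all package errors."""


class ValidationError(BudmineError, ValueError):
    """Input failed a documented precondition."""


class ConfigurationError(ValidationError):
    """A simulation or pipeline configuration is inconsistent."""


class ParseError(ValidationError):
    """A file does not conform to its documented dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line


class StageError(BudmineError, RuntimeError):
    """A pipeline stage failed at run time."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
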