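"""Exception hierarchy.

All file-format errors carry the offending path and, where known, the
1-based line number, so that a failing input can be located directly.
"""


class ScaftierError(Exception):
    """Base class for all package errors."""


class ParseError(ScaftierError):
    """A file violated its format; ``path`` and ``line`` locate the problem."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)


class ValidationError(ScaftierError):
    """Parsed content violated a domain invariant (e.g. AGP tiling hole)."""


class ConfigError(ScaftierError):
    """An operation was configured with unusable parameters."""


class InputError(ScaftierError):
    """Inputs are mutually inconsistent (unknown ids, orphan mates, ...)."""
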