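"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (config 2, validation 3,
numeric degeneracy 4).
"""


class OxichromError(Exception):
    """Base class for all package errors."""


class ConfigError(OxichromError):
    """Bad user configuration: unknown state label, infeasible fractions, ..."""


class ValidationError(OxichromError):
    """Malformed or inconsistent input data."""


class ParseError(ValidationError):
    """Malformed file content; message names the offending line number."""

    def __init__(self, path, lineno, message):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class DegenerateError(OxichromError):
    """A quantity is undefined on this input (zero variance, zero summit sum, ...)."""
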