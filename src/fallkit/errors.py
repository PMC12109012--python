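"""Exception hierarchy shared across fallkit."""


class FallkitError(Exception):
    """Base class for all fallkit-specific errors."""


class InvalidInputError(FallkitError, ValueError):
    """Raised when an input value violates an operation's precondition."""


class DegenerateStatisticsError(FallkitError, ValueError):
    """Raised when normalization statistics are undefined (zero variance)."""


class TraceTooShortError(FallkitError, ValueError):
    """Raised when a trace is shorter than one observation window."""


class TraceParseError(FallkitError, ValueError):
    """Raised on malformed rows in a SisFall-style trace file."""

    def __init__(self, path, line_number, message):
        self.path = path
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class ReassemblyError(FallkitError, RuntimeError):
    """Raised when no packet of an event window was delivered (event lost)."""


class UndefinedMetricError(FallkitError, ZeroDivisionError):
    """Raised when a confusion-matrix metric has a zero denominator."""


class ConfigurationError(FallkitError, ValueError):
    """Raised on inconsistent configuration (bad split, unknown activity...)."""
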