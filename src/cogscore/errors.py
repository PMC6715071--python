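"""Exception hierarchy shared across the package."""


class CogscoreError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CogscoreError, ValueError):
    """A scalar argument is outside its documented domain."""


class InvalidWeightsError(CogscoreError, ValueError):
    """Weight vector is all-zero, negative, or inconsistent with its specs."""


class IncompleteBatteryError(CogscoreError, ValueError):
    """A subject has too few assessments present to score."""


class InsufficientDataError(CogscoreError, ValueError):
    """Too few usable subjects for the requested fit or test."""


class UndefinedCorrelationError(CogscoreError, ValueError):
    """Pearson correlation requested on constant or too-short input."""


class DegenerateLabelsError(CogscoreError, ValueError):
    """ROC analysis requested with only one class present."""


class ConfigError(CogscoreError, ValueError):
    """A generator or run configuration violates its invariants."""


class ParseError(CogscoreError, ValueError):
    """A cohort file row could not be parsed; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
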