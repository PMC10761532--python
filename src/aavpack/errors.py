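"""Exception hierarchy shared across the package."""


class AavpackError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(AavpackError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(AavpackError):
    """A configuration file or config object is invalid or inconsistent."""


class SchemaError(AavpackError):
    """A data file does not match the expected column schema."""


class IonParseError(AavpackError):
    """A row of an ion event file could not be parsed."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class EmptyInputError(AavpackError):
    """An operation received no data to work on."""


class NoBandsError(AavpackError):
    """A gel lane contains no detectable bands above baseline."""


class UndefinedProfileError(AavpackError):
    """A termination profile cannot be formed (all-zero abundances)."""


class UndefinedRatioError(AavpackError, ZeroDivisionError):
    """A ratio with a zero denominator was requested."""
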