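"""Exception hierarchy shared across the package."""


class IRIndicesError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(IRIndicesError):
    """A biochemical measurement violates its physical constraint (e.g. <= 0)."""

    def __init__(self, field: str, value) -> None:
        self.field = field
        self.value = value
        super().__init__(f"invalid measurement for {field!r}: {value!r} (must be > 0)")


class UndefinedIndexError(IRIndicesError):
    """An index is mathematically undefined for the given inputs."""


class DomainError(IRIndicesError):
    """An input lies outside a model backend's declared validity domain."""

    def __init__(self, field: str, value, low, high) -> None:
        self.field = field
        self.value = value
        self.low = low
        self.high = high
        super().__init__(
            f"{field} = {value!r} outside validity domain [{low}, {high}]"
        )


class ConfigurationError(IRIndicesError):
    """An invalid or missing configuration."""


class InsufficientDataError(IRIndicesError):
    """Too few observations to carry out an estimation step."""


class CalibrationError(IRIndicesError):
    """Distribution calibration inputs are inconsistent (e.g. unordered quantiles)."""


class SchemaError(IRIndicesError):
    """A cohort table does not conform to the expected column schema."""

    def __init__(self, missing_columns) -> None:
        self.missing_columns = list(missing_columns)
        super().__init__(
            "cohort file is missing mandatory columns: "
            + ", ".join(self.missing_columns)
        )


class PipelineError(IRIndicesError):
    """A pipeline stage precondition failed (e.g. empty reference group)."""
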