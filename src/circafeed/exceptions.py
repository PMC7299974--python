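"""Package-specific error types.

All errors raised by circafeed derive from :class:`CircafeedError` so callers
can catch the whole family with one except clause.
"""


class CircafeedError(Exception):
    """Base class for all circafeed errors."""


class UnknownItemError(CircafeedError, KeyError):
    """An intake item has no entry in the energy-density table."""

    def __init__(self, item: str):
        super().__init__(f"no energy density known for item {item!r}")
        self.item = item


class UndefinedPreferenceError(CircafeedError, ValueError):
    """A preference index/fraction is requested with a zero denominator."""


class MissingBinError(CircafeedError, ValueError):
    """Choice and baseline tables do not cover the same time-bin grid."""


class GridError(CircafeedError, ValueError):
    """Time bins do not tile the requested interval (gaps or overlaps)."""


class InsufficientFractionsError(CircafeedError, ValueError):
    """Too few dialysate fractions before or after the snack time."""


class DesignError(CircafeedError, ValueError):
    """The harmonic regression design matrix is rank deficient."""


class UndefinedPeakError(CircafeedError, ValueError):
    """Acrophase requested for a fit with zero amplitude."""


class SchemaError(CircafeedError, ValueError):
    """An input table is missing columns or contains invalid values."""


class SampleMismatchError(CircafeedError, ValueError):
    """Expression matrix and sample metadata do not describe the same samples."""


class EmptyInputError(CircafeedError, ValueError):
    """An input table contains no data rows."""


class ConfigError(CircafeedError, ValueError):
    """A simulation configuration is internally inconsistent."""
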