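"""Exception hierarchy shared across pipeline stages."""


class RarpipeError(Exception):
    """Base class for all package errors."""


class FormatError(RarpipeError):
    """Input file does not conform to the expected layout (e.g. missing column)."""


class DataError(RarpipeError):
    """Input file parses but its content violates a data contract."""


class ConfigError(RarpipeError):
    """A configuration value is invalid or inconsistent."""


class EmptySeriesError(DataError):
    """A series contains no usable epochs for the requested operation."""


class InsufficientDataError(DataError):
    """Not enough observations to run the requested estimator."""


class DegenerateFeatureError(DataError):
    """A feature column has zero variance and cannot be standardized."""


class CollinearityError(DataError):
    """Design matrix is rank deficient."""


class UndefinedEffectError(DataError):
    """An effect size is undefined (e.g. zero pooled standard deviation)."""
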