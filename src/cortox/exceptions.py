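"""Exception hierarchy shared across the package."""


class CortoxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CortoxError, ValueError):
    """Invalid parameter or configuration value."""


class InsufficientDataError(CortoxError, ValueError):
    """Record too short (or too few events) for the requested operation."""


class RangeError(CortoxError, ValueError):
    """Requested grid or interval lies outside the available data span."""


class SchemaError(CortoxError, ValueError):
    """Missing or malformed channel, feature, or group label."""


class ShapeError(CortoxError, ValueError):
    """Incompatible array lengths or sampling intervals."""


class IllConditionedError(CortoxError, ValueError):
    """Regression design matrix is rank deficient or numerically singular."""


class DegenerateStatisticError(CortoxError, ValueError):
    """Statistic undefined for the given inputs (e.g. zero variance)."""
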