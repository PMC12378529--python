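"""Exception hierarchy for glycotrack.

All library errors derive from :class:`GlycotrackError` so callers (and the
CLI) can distinguish input-validation problems from configuration problems.
"""


class GlycotrackError(Exception):
    """Base class for all glycotrack errors."""


class DomainError(GlycotrackError, ValueError):
    """An input value lies outside the mathematical domain of an operation
    (non-positive concentration, sub-threshold A1c, zero-length span, ...)."""


class ValidationError(GlycotrackError, ValueError):
    """Structured input failed validation (bad CSV row, duplicate years,
    missing sex, unknown unit tag)."""


class ConfigError(GlycotrackError, ValueError):
    """A configuration value is unknown or inconsistent (unknown metric name,
    unknown archetype, mixture weights that do not sum to one)."""


class DegenerateGeometryError(DomainError):
    """The two anchor half-lives coincide, so the two-point line through the
    ratio anchors is undefined."""


class InsufficientDataError(ValidationError):
    """An operation needs more observations than the series provides
    (e.g. forecasting requires at least two annual panels)."""
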