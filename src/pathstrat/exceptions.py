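"""Exception hierarchy for pathstrat.

All pathstrat errors derive from :class:`PathstratError` so callers can catch
the whole family; the leaves distinguish file-format problems from value-range
and configuration problems.
"""


class PathstratError(Exception):
    """Base class for all pathstrat errors."""


class FormatError(PathstratError):
    """A file does not follow the documented dialect (missing header/column,
    unknown role token, interaction without inputs, ...)."""


class ParseError(PathstratError):
    """A cell that should be numeric is not; the message names row and column."""


class RangeError(PathstratError):
    """A value violates its domain (e.g. methylation beta outside [0, 1])."""


class ValidationError(PathstratError):
    """A table violates a semantic invariant (duplicate sample ids,
    non-positive survival time, non-binary event indicator)."""


class ConfigError(PathstratError):
    """An invalid configuration (inconsistent thresholds, pathway sizes
    exceeding the gene universe, ...)."""
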