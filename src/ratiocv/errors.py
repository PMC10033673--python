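"""Exception hierarchy.

All errors derive from :class:`RatioCVError` so callers can catch the
package's failures with one clause; each also subclasses ``ValueError``
to behave sensibly in generic numeric code.
"""


class RatioCVError(ValueError):
    """Base class for all ratiocv errors."""


class InsufficientDataError(RatioCVError):
    """Too few records to compute the requested statistic."""


class DomainError(RatioCVError):
    """Input values outside the mathematical domain of the operation
    (non-positive values for logs/reciprocals, non-positive mean for CV,
    inconsistent moment sets, ...)."""


class ConfigurationError(RatioCVError):
    """Invalid run or simulation configuration (bad ranges, missing
    columns, malformed parameters)."""


class EmptyResultError(RatioCVError):
    """A filtering stage removed every record or group."""
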