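"""Exception hierarchy.

All package errors derive from :class:`GWTrendError` so callers can catch
broadly; the subclasses distinguish user-configuration mistakes from data
problems and from degenerate numerical situations.
"""


class GWTrendError(Exception):
    """Base class for all errors raised by gwtrend."""


class ConfigurationError(GWTrendError):
    """A parameter, option or column mapping is invalid."""


class ValidationError(GWTrendError):
    """Input data violate a documented contract (bad value, bad row)."""


class StateError(GWTrendError):
    """An operation was applied to a table in the wrong scale state."""


class DegenerateDataError(GWTrendError):
    """Data are formally valid but make the requested statistic undefined
    (zero variance, coincident stations, singular local design)."""
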