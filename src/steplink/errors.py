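"""Exception hierarchy for steplink."""


class SteplinkError(Exception):
    """Base class for all steplink errors."""


class DataError(SteplinkError):
    """A record or input table violates a structural invariant."""


class ConfigError(SteplinkError):
    """A step list, simulation config or pipeline config is invalid."""


class DialectError(SteplinkError):
    """An operation requires full birth dates but the tables carry only
    birth year/month (the indirect-only dialect)."""
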