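"""Exception hierarchy.

Two broad families map onto the CLI exit codes: :class:`DataError` (bad or
degenerate input data, exit 1) and :class:`ConfigError` (bad configuration,
exit 2).
"""


class BafkitError(Exception):
    """Base class for all package errors."""


class DataError(BafkitError):
    """Input data is malformed, degenerate, or violates an operation's contract."""


class ConfigError(BafkitError):
    """Configuration file or option is invalid."""


class PlateMapError(DataError):
    """Plate map is missing wells/roles or references unknown wells."""


class DegenerateControlsError(DataError):
    """Control conditions coincide or are ordered wrongly (e.g. F100 <= F0)."""


class ParameterDomainError(DataError):
    """Model parameters outside their mathematical domain."""


class NoInflectionError(DataError):
    """The fitted sigmoid has no inflection point (H*S <= 1); maximal rate undefined."""


class NoTransitionError(DataError):
    """A melt curve shows no unfolding transition (no positive dF/dT)."""
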