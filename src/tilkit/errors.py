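"""Exception hierarchy shared across the toolkit.

Config problems (bad parameters, malformed run configuration) and data
problems (malformed or degenerate input tables) are kept distinct so the
command-line layer can map them to different exit codes.
"""


class TilkitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(TilkitError):
    """Invalid configuration or parameter value."""


class DataError(TilkitError):
    """Malformed, inconsistent, or degenerate input data."""


class EmptyRepertoireError(DataError):
    """A repertoire has no clones left (e.g. after productive filtering)."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined on the given data (e.g. no events for a
    log-rank test, zero variance for a correlation, or a survival curve
    that never reaches the median)."""
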