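"""Exception hierarchy shared by all tmtdyn modules."""


class TmtdynError(Exception):
    """Base class for all tmtdyn errors."""


class FormatError(TmtdynError, ValueError):
    """An input file does not conform to its expected format."""


class ValidationError(TmtdynError, ValueError):
    """Parsed data violates an invariant (duplicates, negative intensities, ...)."""


class ConfigurationError(TmtdynError, ValueError):
    """Design/table mismatch or an unknown group, channel or plex was requested."""


class UndefinedStatisticError(TmtdynError, ZeroDivisionError):
    """A statistic is undefined for the given input (e.g. zero available sites)."""


class InsufficientReplicationError(TmtdynError, ValueError):
    """A test was requested with fewer than two replicates in a group."""


class DegenerateVarianceError(TmtdynError, ValueError):
    """Both groups of a two-sample test have zero variance."""
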