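"""Exception hierarchy for pinchbind."""


class PinchbindError(Exception):
    """Base class for all pinchbind errors."""


class InvalidParameterError(PinchbindError, ValueError):
    """A numeric parameter violates its precondition (e.g. non-positive duration)."""


class ConfigurationError(PinchbindError, ValueError):
    """A design/population/analysis configuration is internally inconsistent."""


class UsageError(PinchbindError, TypeError):
    """An operation was applied to the wrong kind of object (e.g. wrong channel)."""


class DataError(PinchbindError, ValueError):
    """Input data violate a structural contract (non-finite samples, missing events)."""


class DegenerateDataError(DataError):
    """Data are structurally valid but statistically degenerate (e.g. zero variance)."""


class NoSolutionError(PinchbindError, ValueError):
    """A solver's target is unreachable within its admissible domain."""
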