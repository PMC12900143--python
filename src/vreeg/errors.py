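"""Exception hierarchy shared across the package."""


class VreegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(VreegError, ValueError):
    """An input parameter violates its documented domain."""


class PolicyError(VreegError):
    """An ordering policy was invoked for an actor it does not apply to."""


class ScenarioComplete(VreegError):
    """The demand schedule is exhausted; no further days can be stepped."""


class ConfigError(VreegError, ValueError):
    """A run or scenario configuration is malformed."""


class QualityError(VreegError):
    """A recording lacks the quality series required for filtering."""


class EventNotFoundError(VreegError, KeyError):
    """A requested time-event marker is absent from a recording."""


class ResolutionError(VreegError, ValueError):
    """An epoch is too short for the requested spectral resolution."""


class BaselineError(VreegError):
    """Performance metrics requested without baseline statistics."""


class MontageError(VreegError, KeyError):
    """An electrode label is not part of the montage."""


class SampleError(VreegError, ValueError):
    """A statistical routine received a degenerate or too-small sample."""
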