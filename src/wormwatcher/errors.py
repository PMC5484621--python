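"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A user-supplied configuration (well grid, schedule, simulation) is invalid."""


class InvalidEpochError(RuntimeError):
    """An imaging epoch lacks the samples required to compute a metric.

    Raised when, e.g., a 60-s trace has no pre-stimulus or no post-stimulus
    frame pairs inside an epoch.  Callers that batch over epochs should catch
    this and mark the epoch invalid rather than silently substituting zeros.
    """


class InsufficientDataError(ValueError):
    """Too few animals or samples for the requested statistic."""
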