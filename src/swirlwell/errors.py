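"""Exception types shared across the package."""


class SwirlwellError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(SwirlwellError):
    """A well/orbit/fluid configuration violates a physical invariant."""


class UndefinedMetricError(SwirlwellError):
    """A metric has no value for this series (e.g. OSI of a zero-stress series).

    Carries a machine-readable ``reason`` code so callers can record *why*
    rather than silently substituting zero.
    """

    def __init__(self, metric: str, reason: str):
        self.metric = metric
        self.reason = reason
        super().__init__(f"{metric} is undefined: {reason}")


class DegenerateReferenceError(UndefinedMetricError):
    """The mean WSS vector vanishes, so no reference direction exists.

    transWSS and CFI need the mean-vector direction; callers may fall back
    to the minimized variants, which are defined for any series.
    """

    def __init__(self, metric: str):
        super().__init__(metric, "zero-mean reference vector")


class FieldFormatError(SwirlwellError):
    """An input field file violates the documented dialect."""
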