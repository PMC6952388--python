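"""Exception hierarchy for the axonquant pipeline."""


class AxonquantError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AxonquantError, ValueError):
    """A parameter violates its documented domain (e.g. non-positive length)."""


class InvalidInputError(AxonquantError, ValueError):
    """An input object violates a precondition (e.g. empty stack, all-excluded profile)."""


class InvalidRegionError(AxonquantError, ValueError):
    """Requested arc-length region lies outside the trace."""


class OutOfBoundsError(AxonquantError, ValueError):
    """A sample point or trace vertex falls outside the image."""


class DegenerateProfileError(AxonquantError, ValueError):
    """Profile has zero variance; autocorrelation is undefined."""


class TracingFailedError(AxonquantError, RuntimeError):
    """Ridge following found no ridge above background."""


class ReconciliationError(AxonquantError, ValueError):
    """Animal identifiers could not be matched across tables."""

    def __init__(self, message, offenders=()):
        super().__init__(message)
        self.offenders = list(offenders)
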