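"""Exception hierarchy.

Every error raised by magflow derives from :class:`MagflowError` so callers
can catch the package's failures with one clause while still discriminating
I/O problems from bad parameters or failed fits.
"""


class MagflowError(Exception):
    """Base class for all magflow errors."""


class FormatError(MagflowError):
    """A file could not be interpreted in the requested format."""


class ValidationError(MagflowError):
    """Input data violate a documented invariant (negative intensity, bad OD, ...)."""


class ChannelError(MagflowError):
    """A required detector channel is absent from the event table."""


class SampleSizeError(MagflowError):
    """Too few events for the requested statistic."""


class ParameterError(MagflowError):
    """A model or generator parameter violates its invariants."""


class FitError(MagflowError):
    """A model fit failed to converge or the design is degenerate."""


class MetadataError(MagflowError):
    """Acquisition metadata required for the computation is missing or assumed."""


class ConfigurationError(MagflowError):
    """A pipeline configuration is incomplete or inconsistent."""
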