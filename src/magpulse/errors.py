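"""Exception hierarchy shared across the package.

Every error raised on purpose derives from :class:`MagpulseError`, so callers
can catch one type at the CLI boundary.  The leaf classes mirror the distinct
failure modes of the public API: bad physical parameters, insufficient
numerical resolution, malformed configuration, schema violations in tabular
input, and statistically degenerate samples.
"""


class MagpulseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(MagpulseError, ValueError):
    """A physical or numerical parameter violates its invariant."""


class ResolutionError(MagpulseError, ValueError):
    """The requested sampling grid cannot resolve the waveform."""


class ConfigurationError(MagpulseError, ValueError):
    """A configuration file or option set is malformed."""


class SchemaError(MagpulseError, ValueError):
    """A tabular input record violates the declared schema."""


class DegenerateTableError(MagpulseError, ValueError):
    """A contingency table has a zero margin."""


class DegenerateInputError(MagpulseError, ValueError):
    """A statistical sample is degenerate for the requested test."""


class SampleSizeError(MagpulseError, ValueError):
    """A sample is too small for the requested test."""


class UndefinedRatioError(MagpulseError, ZeroDivisionError):
    """A ratio criterion cannot be evaluated (zero denominator)."""


class DomainError(MagpulseError, ValueError):
    """A design target lies outside the solvable domain."""
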