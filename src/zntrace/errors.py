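"""Exception hierarchy for zntrace.

All package-specific failures derive from :class:`ZnTraceError` so callers can
catch one base class at pipeline boundaries.
"""


class ZnTraceError(Exception):
    """Base class for all zntrace errors."""


class IncompleteRatioSetError(ZnTraceError):
    """A ratio set is missing one of the required denominator isotopes."""


class DomainError(ZnTraceError):
    """An input value is outside the mathematical domain of an operation."""


class UnresolvableMixtureError(ZnTraceError):
    """The two sources are isotopically too similar to unmix."""


class DegenerateSourceError(ZnTraceError):
    """A source composition makes the mixing denominator non-positive."""


class InsufficientReplicationError(ZnTraceError):
    """Fewer replicates than the statistic requires (n >= 2)."""


class UnbracketedSampleError(ZnTraceError):
    """A sample measurement lies outside the bracketing-standard envelope."""


class PairingError(ZnTraceError):
    """Paired arrays have unequal lengths."""


class InfeasibleTargetError(ZnTraceError):
    """A spike target ratio cannot be reached with the given spike."""


class ConfigError(ZnTraceError):
    """A run configuration references undefined entities or bad values."""
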