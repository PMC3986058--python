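"""Exception hierarchy for socgeo.

All errors derive from :class:`SocgeoError` so callers can catch the
package's failures with one clause; the subclasses mirror the failure
modes of the individual stages (I/O schema problems, domain violations,
degenerate inputs, optimizer failures, simulation failures).
"""


class SocgeoError(Exception):
    """Base class for all socgeo errors."""


class SchemaError(SocgeoError):
    """A required column is missing or mis-declared in an input table."""


class ParseError(SocgeoError):
    """A cell could not be parsed as the declared type."""


class ValidationError(SocgeoError):
    """A value violates a physical-range invariant (e.g. SOC <= 0)."""


class DomainError(SocgeoError, ValueError):
    """A function argument is outside its mathematical domain."""


class DimensionError(SocgeoError):
    """A grid or array has an invalid or inconsistent shape."""


class InsufficientDataError(SocgeoError):
    """Not enough observations for the requested statistic."""


class DegenerateDataError(SocgeoError):
    """Input is degenerate for the requested operation (e.g. zero variance)."""


class NoPairsError(SocgeoError):
    """No usable point pairs for a semivariogram (coincident points or empty cone)."""


class FitError(SocgeoError):
    """Model fitting failed to converge; carries optimizer diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class GenerationError(SocgeoError):
    """Random-field generation failed (covariance not positive definite)."""


class DuplicatePointsError(SocgeoError):
    """The kriging system is singular; input locations must be deduplicated."""


class ConfigError(SocgeoError):
    """A pipeline configuration file is invalid."""
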