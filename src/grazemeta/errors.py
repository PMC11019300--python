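"""Exception hierarchy for grazemeta.

All package-specific failures derive from :class:`GrazemetaError` so callers
can catch one type at the pipeline boundary.
"""


class GrazemetaError(Exception):
    """Base class for all grazemeta errors."""


class ConfigError(GrazemetaError):
    """Invalid simulation or run configuration; message names the field."""


class SchemaError(GrazemetaError):
    """Input table does not match the documented column schema."""


class ValidationError(GrazemetaError):
    """A row violates a value constraint (e.g. non-positive mean)."""


class HarmonizationError(GrazemetaError):
    """A categorical label cannot be mapped to the closed vocabulary."""


class AnalysisError(GrazemetaError):
    """An analysis precondition is not met (too few effects, zero variance,
    rank-deficient design, ...)."""
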