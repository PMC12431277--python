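"""Exception hierarchy shared across the package."""


class NCIIError(ValueError):
    """Base class for all package-specific errors."""


class SchemaError(NCIIError):
    """Input table is missing columns or cannot be mapped to the schema."""


class ValidationError(NCIIError):
    """A table or design violates a structural invariant."""


class DesignError(NCIIError):
    """The mating design is inconsistent (e.g. a token used as both sexes)."""


class InsufficientDataError(NCIIError):
    """Too few observations for the requested computation."""


class FitError(NCIIError):
    """A model cannot be constructed or fitted on the given data."""


class PipelineError(NCIIError):
    """A pipeline stage failed."""
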