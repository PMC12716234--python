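"""Exception hierarchy shared across guvmech modules."""


class GuvmechError(Exception):
    """Base class for all guvmech-specific errors."""


class InvalidContourError(GuvmechError):
    """A contour is degenerate (fewer than 3 vertices, zero area, ...)."""


class ConfigurationError(GuvmechError):
    """Missing or inconsistent experiment configuration (e.g. unknown medium)."""


class SchemaError(GuvmechError):
    """An input table lacks a required feature column or has malformed data."""


class EstimationError(GuvmechError):
    """An estimator could not produce a modulus (e.g. non-positive slope)."""
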