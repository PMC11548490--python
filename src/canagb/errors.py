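"""Exception hierarchy for the biomass-estimation pipeline."""


class CanagbError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CanagbError, ValueError):
    """An argument violates a precondition (non-positive count, factor < 1, ...)."""


class ConfigurationError(CanagbError):
    """A configuration is inconsistent (missing stage anchor, empty band interval, ...)."""


class FormatError(CanagbError):
    """A raster file violates the expected dialect (missing wavelengths, count mismatch)."""


class EmptyRegionError(CanagbError):
    """A plot region contains no valid pixels."""


class DegenerateTextureError(CanagbError):
    """No valid pixel pairs exist at the requested co-occurrence offsets."""


class SchemaError(CanagbError):
    """A feature table is missing columns required by a scheme."""


class InsufficientDataError(CanagbError):
    """Too few samples for the requested split or fit."""


class InvariantViolationError(CanagbError):
    """An internal invariant was violated (unnormalized GLCM, scheme name collision)."""
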