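"""Exception hierarchy shared across the package."""


class Ki67SegError(Exception):
    """Base class for all package errors."""


class ParameterError(Ki67SegError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(Ki67SegError, ValueError):
    """A model/network/pipeline configuration is internally inconsistent."""


class DegenerateInputError(Ki67SegError, ValueError):
    """Input is structurally valid but degenerate for the operation (e.g. empty mask)."""


class SchemaError(Ki67SegError, ValueError):
    """A manifest/config file violates its schema; message names the offending keys."""


class ShapeError(Ki67SegError, ValueError):
    """Array shapes are incompatible with the operation."""


class TrainingDivergenceError(Ki67SegError, RuntimeError):
    """Training produced a non-finite loss; message reports the epoch."""
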