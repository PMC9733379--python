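"""Exception hierarchy shared by all pipeline stages."""


class UavCanopyError(Exception):
    """Base class for all package errors."""


class ValidationError(UavCanopyError, ValueError):
    """Invalid input data or configuration."""


class DegenerateGeometryError(ValidationError):
    """Geometry too degenerate to process (collinear points, vertical plane, ...)."""


class NumericError(UavCanopyError, ArithmeticError):
    """A numeric routine failed to converge or produced an unusable result."""


class FormatError(UavCanopyError, IOError):
    """Malformed or unsupported file content."""
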