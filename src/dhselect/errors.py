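"""Exception types shared across the package."""


class DhselectError(Exception):
    """Base class for package-specific errors."""


class InvalidArgument(DhselectError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(DhselectError, ValueError):
    """A file does not conform to its declared format."""


class MissingCellError(DhselectError, KeyError):
    """A required trait × environment cell has no observations."""


class EstimationError(DhselectError, RuntimeError):
    """A statistical estimate is undefined for the given data."""
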