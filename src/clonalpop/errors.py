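"""Exception types shared across the package."""


class ClonalpopError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClonalpopError):
    """Raised when an input file or in-memory object violates its contract."""


class ParseError(ClonalpopError):
    """Raised when a file cannot be parsed at all (syntax-level failure)."""
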