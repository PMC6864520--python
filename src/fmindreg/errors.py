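"""Typed exceptions shared across the package."""


class FmindregError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(FmindregError, ValueError):
    """A parameter violates an operation's contract."""


class OutOfBoundsError(FmindregError, IndexError):
    """A voxel coordinate lies outside the image domain."""


class ShapeMismatchError(FmindregError, ValueError):
    """Two arrays that must share a shape do not."""


class IncompatibleDescriptorsError(FmindregError, ValueError):
    """Descriptor fields differ in shape or search offsets."""


class UnsupportedFormatError(FmindregError, ValueError):
    """File extension or payload not supported by the I/O layer."""


class LandmarkParseError(FmindregError, ValueError):
    """Malformed landmark file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
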