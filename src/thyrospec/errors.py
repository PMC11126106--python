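"""Exception types raised across the package."""


class ThyrospecError(Exception):
    """Base class for package errors."""


class CorruptFileError(ThyrospecError, IOError):
    """Raw stream length does not match the header's declared geometry."""


class UnsupportedFormatError(ThyrospecError, ValueError):
    """File declares an interleave or dtype the reader does not support."""


class DegenerateReferenceError(ThyrospecError, ValueError):
    """White reference does not exceed the dark reference somewhere."""


class EmptyClassError(ThyrospecError, ValueError):
    """A requested label class has no pixels."""


class LeakageError(ThyrospecError, ValueError):
    """A case id appears on both sides of a train/validation/test boundary."""


class ShapeError(ThyrospecError, ValueError):
    """Array shape incompatible with the operation's contract."""


class ConfigError(ThyrospecError, ValueError):
    """Invalid or unknown configuration."""
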