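"""Exception hierarchy for the graylift codec."""


class GrayliftError(Exception):
    """Base class for all graylift errors."""


class InvalidInputError(GrayliftError, ValueError):
    """An argument violates a documented precondition (shape, range, emptiness)."""


class ConfigError(GrayliftError, ValueError):
    """A configuration is inconsistent (wrong input count, bad precision, ...)."""


class NumericError(GrayliftError, ArithmeticError):
    """Non-finite values where finite ones are required."""


class CorruptStreamError(GrayliftError, ValueError):
    """A compressed stream is truncated, tampered with, or internally inconsistent."""


class ModelMismatchError(GrayliftError, ValueError):
    """The decoder's model bundle does not match the one recorded in the stream."""


class CodecError(GrayliftError, RuntimeError):
    """A base codec (PNG / JPEG-XL) failed or is unavailable."""


class TrainingError(GrayliftError, RuntimeError):
    """Training diverged or produced non-finite losses."""


class DataError(GrayliftError, ValueError):
    """A dataset directory contains no readable images."""
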