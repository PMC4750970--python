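"""Exception types raised across the pipeline.

All inherit from :class:`PollenVisionError` so callers can catch the whole
family; most also inherit a matching builtin (``ValueError`` etc.) so generic
handling keeps working.
"""


class PollenVisionError(Exception):
    """Base class for all package errors."""


class BoundsError(PollenVisionError, IndexError):
    """A coordinate or rectangle falls outside the image plane."""


class ParameterError(PollenVisionError, ValueError):
    """A configuration parameter violates its documented range."""


class InputError(PollenVisionError, ValueError):
    """Input data violates a precondition (shape mismatch, missing mask...)."""


class FormatError(PollenVisionError, ValueError):
    """A file on disk does not match the expected on-disk format."""


class StateError(PollenVisionError, RuntimeError):
    """An operation was called on an object in the wrong state (untrained model)."""
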