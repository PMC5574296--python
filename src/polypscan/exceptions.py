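"""Exception hierarchy for polypscan.

Everything derives from :class:`PolypscanError` so callers can catch the
package's failures with a single except clause; the subclasses distinguish
I/O, geometry and data problems.
"""


class PolypscanError(Exception):
    """Base class for all polypscan errors."""


class DecodeError(PolypscanError, IOError):
    """A video container or image file could not be decoded."""


class EmptyInputError(PolypscanError, ValueError):
    """A source (video, directory, dataset) contained no usable items."""


class TooSmallError(PolypscanError, ValueError):
    """A frame or crop is smaller than the sliding-window size."""


class BoundsError(PolypscanError, ValueError):
    """A rectangle, ROI or marker lies outside its parent image."""


class ShapeError(PolypscanError, ValueError):
    """An array does not have the required shape or length."""


class ConfigError(PolypscanError, ValueError):
    """An unknown or inconsistent configuration value."""


class DataError(PolypscanError, ValueError):
    """Input data violates a precondition (non-finite values, etc.)."""


class DegenerateLabelsError(PolypscanError, ValueError):
    """A training set contains fewer than two classes."""
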