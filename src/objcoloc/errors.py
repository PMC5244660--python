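"""Exception hierarchy shared by all objcoloc modules."""


class ObjcolocError(Exception):
    """Base class for all objcoloc errors."""


class FormatError(ObjcolocError):
    """File could not be read or is not a supported image format."""


class UnsupportedLayoutError(FormatError):
    """Image layout (multi-plane, RGB, non-integer) is not supported."""


class ValidationError(ObjcolocError):
    """Image data violates a declared constraint (e.g. bit-depth range)."""


class PairingError(ObjcolocError):
    """Two channel files cannot be combined into an analysis pair."""


class DegenerateHistogramError(ObjcolocError):
    """Histogram-based thresholding is impossible (constant image)."""


class DegenerateChannelError(ObjcolocError):
    """A channel carries no signal (all zero) and cannot be analyzed."""


class EmptyScopeError(ObjcolocError):
    """An analysis mask selects no pixels."""


class CalibrationError(ObjcolocError):
    """FRET bleed-through calibration failed (empty signal mask)."""


class GenerationError(ObjcolocError):
    """A synthetic scene request cannot be realized geometrically."""
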