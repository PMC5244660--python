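"""Background subtraction and intensity-range equalization.

The batch pipeline's first two steps: estimate the background of each
channel from the population below a triangle (Zack) threshold, subtract
it, and stretch both channels independently to the full bit-depth range
so that differing detector gains or expression levels do not bias the
downstream object thresholds and the 2D histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateChannelError, DegenerateHistogramError
from .io_formats import ChannelImage, ImagePair


@dataclass(frozen=True)
class PreprocessReport:
    """What preprocessing did to one channel."""

    triangle_threshold: float
    background_level: float
    scale_factor: float = 1.0


def histogram_bins(bit_depth: int) -> int:
    """Bin count for intensity histograms: one bin per level for 8/12-bit,
    4096 equal-width bins for 16-bit."""
    return 2**bit_depth if bit_depth <= 12 else 4096


def intensity_histogram(image: ChannelImage) -> tuple[np.ndarray, float]:
    """Full-range histogram of an image; returns (counts, bin_width)."""
    nbins = histogram_bins(image.bit_depth)
    width = (image.max_value + 1) / nbins
    idx = np.minimum((np.asarray(image.pixels, dtype=np.float64) / width).astype(np.int64),
                     nbins - 1)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    return counts, width


def _triangle_bin(counts: np.ndarray) -> int:
    """Zack triangle threshold on a histogram, returned as a bin index.

    Draws the line from the histogram peak to the furthest nonempty bin
    and returns the bin strictly between them whose perpendicular distance
    to that line is maximal.
    """
    nonempty = np.flatnonzero(counts)
    if len(nonempty) < 2:
        raise DegenerateHistogramError(
            "constant image: triangle threshold needs at least 2 distinct levels"
        )
    peak = int(np.argmax(counts))
    lo, hi = int(nonempty[0]), int(nonempty[-1])
    # furthest nonempty bin from the peak (ties resolved toward the bright side)
    tail = hi if (hi - peak) >= (peak - lo) else lo
    x1, y1 = float(peak), float(counts[peak])
    x2, y2 = float(tail), float(counts[tail])
    inner = np.arange(min(peak, tail) + 1, max(peak, tail))
    if len(inner) == 0:
        # peak and tail are adjacent; the only admissible bin is the tail side
        return int(min(peak, tail) + 1) if tail > peak else int(tail)
    y = counts[inner].astype(np.float64)
    # perpendicular distance to the peak-tail line, up to a constant factor
    dist = np.abs((y2 - y1) * inner - (x2 - x1) * y + x2 * y1 - y2 * x1)
    best = inner[int(np.argmax(dist))]
    return int(best)


def triangle_threshold(image: ChannelImage) -> float:
    """Zack triangle threshold of an image, in intensity units.

    Raises :class:`DegenerateHistogramError` on constant input.
    """
    counts, width = intensity_histogram(image)
    return _triangle_bin(counts) * width


def subtract_background(image: ChannelImage) -> tuple[ChannelImage, PreprocessReport]:
    """Subtract the mean intensity of the sub-threshold population.

    The background estimate is the mean of pixels strictly below the
    triangle threshold (0 if no pixel is below).  Output pixels are
    clamped at 0; bit depth is unchanged.
    """
    thr = triangle_threshold(image)
    px = np.asarray(image.pixels)
    below = px[px < thr]
    background = float(below.mean()) if below.size else 0.0
    out = np.maximum(px - int(round(background)), 0)
    report = PreprocessReport(triangle_threshold=thr, background_level=background)
    return image.with_pixels(out.astype(px.dtype)), report


def equalize_channel(image: ChannelImage) -> tuple[ChannelImage, float]:
    """Min-max stretch one channel to [0, 2**bit_depth - 1].

    Returns the stretched image and the applied scale factor.  A channel
    with zero maximum cannot be stretched and raises
    :class:`DegenerateChannelError`.
    """
    px = np.asarray(image.pixels, dtype=np.float64)
    lo, hi = px.min(), px.max()
    if hi <= 0 or hi == lo:
        raise DegenerateChannelError(
            f"{image.source_id or 'channel'}: no dynamic range to equalize"
        )
    scale = image.max_value / (hi - lo)
    out = np.rint((px - lo) * scale)
    return image.with_pixels(out.astype(np.int64)), float(scale)


def equalize_intensity_range(pair: ImagePair) -> tuple[ImagePair, float, float]:
    """Independently stretch both channels to the full bit-depth range.

    After the call both channels span [0, max]; returns the pair plus the
    per-channel scale factors.
    """
    a, scale_a = equalize_channel(pair.a)
    b, scale_b = equalize_channel(pair.b)
    return ImagePair(a, b), scale_a, scale_b
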