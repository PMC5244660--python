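"""Object recognition and mask algebra.

Thresholding (maximum-entropy, iterative intermeans, manual), binary
watershed separation of touching objects, combination (union) and
colocalization (intersection) masks, particle analysis with a minimum
area filter, and the colocalization area fraction — the object-based
half of the combined coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation

from .errors import DegenerateHistogramError, ValidationError
from .io_formats import ChannelImage
from .preprocess import intensity_histogram

#: 8-connectivity structuring element for component labeling
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BinaryMask:
    """Boolean object mask, same dimensions as its source channel."""

    pixels: np.ndarray
    source_role: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class LabeledObjects:
    """Connected components surviving the minimum-area filter."""

    labels: np.ndarray
    objects: list[tuple[int, int, tuple[float, float]]]  # (id, area_px, centroid)

    @property
    def count(self) -> int:
        return len(self.objects)

    @property
    def total_area(self) -> int:
        return int(sum(area for _, area, _ in self.objects))


@dataclass(frozen=True)
class ObjectColocStats:
    count_a: int
    count_b: int
    count_combined: int
    count_coloc: int
    area_a: int
    area_b: int
    area_combined: int
    area_coloc: int
    fraction: float


def _entropy_threshold_bin(counts: np.ndarray) -> int:
    """Kapur-Sahoo-Wong maximum-entropy threshold as a bin index.

    Maximizes the sum of the Shannon entropies of the below (<= t) and
    above (> t) class distributions over all thresholds with two
    nonempty classes.
    """
    p = counts.astype(np.float64)
    total = p.sum()
    if np.count_nonzero(p) < 2:
        raise DegenerateHistogramError("constant image: cannot threshold")
    p /= total
    cumsum = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    cum_plogp = np.cumsum(plogp)
    best_t, best_h = None, -np.inf
    n = len(p)
    for t in range(n - 1):
        w0 = cumsum[t]
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - cum_plogp[t] / w0
        h1 = np.log(w1) - (cum_plogp[-1] - cum_plogp[t]) / w1
        if h0 + h1 > best_h:
            best_h, best_t = h0 + h1, t
    if best_t is None:
        raise DegenerateHistogramError("constant image: cannot threshold")
    return int(best_t)


def _intermeans_threshold_bin(counts: np.ndarray) -> int:
    """Iterative intermeans (IsoData) threshold as a bin index.

    Starting from the midpoint of the nonempty range, iterate
    t <- (mean of class <= t + mean of class > t) / 2 to a fixpoint.
    """
    nonempty = np.flatnonzero(counts)
    if len(nonempty) < 2:
        raise DegenerateHistogramError("constant image: cannot threshold")
    levels = np.arange(len(counts), dtype=np.float64)
    weighted = levels * counts
    t = 0.5 * (nonempty[0] + nonempty[-1])
    for _ in range(1000):
        ti = int(np.floor(t))
        n_lo = counts[: ti + 1].sum()
        n_hi = counts[ti + 1:].sum()
        if n_lo == 0 or n_hi == 0:
            break
        mu_lo = weighted[: ti + 1].sum() / n_lo
        mu_hi = weighted[ti + 1:].sum() / n_hi
        t_new = 0.5 * (mu_lo + mu_hi)
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    return int(np.floor(t))


def threshold_objects(image: ChannelImage, method: str = "max_entropy",
                      manual_value: float | None = None) -> BinaryMask:
    """Binarize a channel into an object mask.

    ``max_entropy``: Kapur maximum-entropy histogram threshold;
    ``default``: iterative intermeans (IsoData);
    ``manual``: the supplied intensity.  Foreground is always strict:
    a pixel belongs to the mask iff its intensity exceeds the threshold.
    """
    role = image.role
    px = np.asarray(image.pixels)
    if method == "manual":
        if manual_value is None:
            raise ValidationError("manual thresholding requires manual_value")
        return BinaryMask(px > manual_value, role)
    if manual_value is not None:
        raise ValidationError("manual_value only applies to method='manual'")
    counts, width = intensity_histogram(image)
    if method == "max_entropy":
        t = _entropy_threshold_bin(counts)
    elif method == "default":
        t = _intermeans_threshold_bin(counts)
    else:
        raise ValidationError(f"unknown threshold method {method!r}")
    # bin index -> intensity: foreground strictly above the bin's upper level
    thr = (t + 1) * width - 1 if width > 1 else float(t)
    return BinaryMask(px > thr, role)


def watershed_split(mask: BinaryMask) -> BinaryMask:
    """Separate touching objects with a classical binary watershed.

    Seeds are the regional maxima of the Euclidean distance transform
    (maxima closer than 2 px are merged); one-pixel watershed lines are
    set to background where basins of distinct seeds meet.  Foreground
    never grows.
    """
    fg = mask.pixels
    if not fg.any():
        return mask
    dist = ndi.distance_transform_edt(fg)
    maxima = morphology.local_maxima(dist, connectivity=2)
    # merge maxima separated by < 2 px by bridging one-pixel gaps
    merged = ndi.binary_dilation(maxima, structure=_CONN8)
    seeds, n_seeds = ndi.label(merged, structure=_CONN8)
    seeds[~maxima] = 0
    if n_seeds <= 1:
        return mask
    basins = segmentation.watershed(-dist, markers=seeds, mask=fg,
                                    watershed_line=True)
    return BinaryMask(basins > 0, mask.source_role)


def combine_masks(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Union of the two object masks (the "Max" of binary images)."""
    if mask_a.shape != mask_b.shape:
        raise ValidationError(f"mask dimensions differ: {mask_a.shape} vs {mask_b.shape}")
    return BinaryMask(mask_a.pixels | mask_b.pixels, "combined")


def intersect_masks(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Intersection of the two object masks (boolean AND)."""
    if mask_a.shape != mask_b.shape:
        raise ValidationError(f"mask dimensions differ: {mask_a.shape} vs {mask_b.shape}")
    return BinaryMask(mask_a.pixels & mask_b.pixels, "coloc")


def analyze_particles(mask: BinaryMask, min_area: int = 25) -> LabeledObjects:
    """8-connected component labeling with a minimum-area filter.

    Components smaller than ``min_area`` pixels are removed from both the
    label image and the object list; the boundary is inclusive (a
    component of exactly ``min_area`` pixels is kept).
    """
    if min_area < 1:
        raise ValidationError("min_area must be >= 1")
    labels, _ = ndi.label(mask.pixels, structure=_CONN8)
    objects = []
    out = np.zeros_like(labels)
    next_id = 0
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        next_id += 1
        out[labels == region.label] = next_id
        objects.append((next_id, int(region.area),
                        (float(region.centroid[0]), float(region.centroid[1]))))
    return LabeledObjects(labels=out, objects=objects)


def coloc_stats(mask_a: BinaryMask, mask_b: BinaryMask,
                min_area: int = 25) -> ObjectColocStats:
    """Object counts, areas, and the colocalization area fraction.

    Particle analysis (with the minimum-area filter applied independently)
    runs on mask A, mask B, their union, and their intersection; the
    fraction is the filtered intersection area over the filtered union
    area, NaN when the union is empty.
    """
    pa = analyze_particles(mask_a, min_area)
    pb = analyze_particles(mask_b, min_area)
    pc = analyze_particles(combine_masks(mask_a, mask_b), min_area)
    px = analyze_particles(intersect_masks(mask_a, mask_b), min_area)
    fraction = (px.total_area / pc.total_area) if pc.total_area > 0 else float("nan")
    return ObjectColocStats(
        count_a=pa.count, count_b=pb.count,
        count_combined=pc.count, count_coloc=px.count,
        area_a=pa.total_area, area_b=pb.total_area,
        area_combined=pc.total_area, area_coloc=px.total_area,
        fraction=float(fraction),
    )
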