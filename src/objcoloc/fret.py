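"""Three-filter sensitized-emission FRET analysis.

The three filter cubes give DONOR (donor emission at donor excitation),
rawFRET (acceptor emission at donor excitation) and ACCEPTOR (acceptor
emission at acceptor excitation).  Single-fluorophore reference samples
calibrate the bleed-through factors

    df = rawFRET / DONOR      (donor-only reference)
    af = rawFRET / ACCEPTOR   (acceptor-only reference)

from which the corrected FRET image and pixelwise apparent efficiency
follow:

    cFRET    = rawFRET - DONOR * df - ACCEPTOR * af
    FRET-Eff = 1 - DONOR / (DONOR + cFRET)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import CalibrationError, DegenerateHistogramError
from .io_formats import ChannelImage
from .object_coloc import BinaryMask
from .preprocess import subtract_background, triangle_threshold


@dataclass(frozen=True)
class FretChannels:
    """Aligned DONOR / rawFRET / ACCEPTOR triplet of one field of view."""

    donor: ChannelImage
    raw_fret: ChannelImage
    acceptor: ChannelImage

    def __post_init__(self) -> None:
        shapes = {self.donor.shape, self.raw_fret.shape, self.acceptor.shape}
        depths = {self.donor.bit_depth, self.raw_fret.bit_depth, self.acceptor.bit_depth}
        if len(shapes) != 1 or len(depths) != 1:
            raise CalibrationError("FRET channels must share dimensions and bit depth")


@dataclass(frozen=True)
class BleedThrough:
    """Calibrated donor/acceptor bleed-through into the rawFRET cube."""

    df: float
    af: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.df) and np.isfinite(self.af)):
            raise CalibrationError("bleed-through factors must be finite")
        if self.df < 0 or self.af < 0:
            raise CalibrationError("bleed-through factors must be >= 0")


@dataclass(frozen=True)
class FretResult:
    cfret: np.ndarray            # signed corrected FRET image
    efficiency: np.ndarray       # NaN off-mask / where undefined
    mean_efficiency: float
    analysis_mask: BinaryMask
    bleed_through: BleedThrough


def _background_subtracted(image: ChannelImage) -> ChannelImage:
    """Triangle-threshold background subtraction; a constant channel
    (e.g. an identically-zero reference channel) passes through as-is."""
    try:
        out, _ = subtract_background(image)
        return out
    except DegenerateHistogramError:
        return image


def _signal_mask(image: ChannelImage) -> np.ndarray:
    try:
        thr = triangle_threshold(image)
    except DegenerateHistogramError:
        return np.zeros(image.shape, dtype=bool)
    return np.asarray(image.pixels) > thr


def bleed_through_factor(reference: FretChannels, kind: str,
                         method: str = "mean_ratio") -> float:
    """Calibrate df or af from a single-fluorophore reference triplet.

    ``kind`` is ``"donor_only"`` (ratio to DONOR) or ``"acceptor_only"``
    (ratio to ACCEPTOR).  Channels are background-subtracted; the signal
    mask is the triangle threshold on the denominator channel.
    ``method="mean_ratio"`` (default) divides the masked means;
    ``method="pixelwise_median"`` takes the median of per-pixel ratios.
    """
    if kind == "donor_only":
        denom_img = _background_subtracted(reference.donor)
    elif kind == "acceptor_only":
        denom_img = _background_subtracted(reference.acceptor)
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    raw = _background_subtracted(reference.raw_fret)
    mask = _signal_mask(denom_img)
    if not mask.any():
        raise CalibrationError(f"{kind} reference: empty signal mask")
    num = np.asarray(raw.pixels, dtype=np.float64)[mask]
    den = np.asarray(denom_img.pixels, dtype=np.float64)[mask]
    if method == "mean_ratio":
        if den.mean() <= 0:
            raise CalibrationError(f"{kind} reference: zero denominator signal")
        return float(num.mean() / den.mean())
    if method == "pixelwise_median":
        pos = den > 0
        if not pos.any():
            raise CalibrationError(f"{kind} reference: zero denominator signal")
        return float(np.median(num[pos] / den[pos]))
    raise ValueError(f"unknown calibration method {method!r}")


def corrected_fret(sample: FretChannels, bt: BleedThrough) -> np.ndarray:
    """Pixelwise bleed-through-corrected FRET image (signed).

    Over-corrected (negative) pixels are retained for diagnostics;
    clamping to zero happens only inside the efficiency formula.
    """
    donor = np.asarray(sample.donor.pixels, dtype=np.float64)
    raw = np.asarray(sample.raw_fret.pixels, dtype=np.float64)
    acceptor = np.asarray(sample.acceptor.pixels, dtype=np.float64)
    return raw - donor * bt.df - acceptor * bt.af


def fret_efficiency(donor: np.ndarray, cfret: np.ndarray,
                    mask: BinaryMask) -> tuple[np.ndarray, float]:
    """Pixelwise apparent FRET efficiency 1 - D/(D + max(cFRET, 0)).

    Defined only on the analysis mask where the donor is positive;
    elsewhere NaN.  Pixels with cFRET <= 0 have efficiency 0.  Returns
    the efficiency map and its mean over defined masked pixels.
    """
    donor = np.asarray(donor, dtype=np.float64)
    cpos = np.maximum(np.asarray(cfret, dtype=np.float64), 0.0)
    m = np.asarray(mask.pixels, dtype=bool)
    if not m.any():
        raise CalibrationError("empty analysis mask")
    eff = np.full(donor.shape, np.nan)
    valid = m & (donor > 0)
    eff[valid] = 1.0 - donor[valid] / (donor[valid] + cpos[valid])
    mean = float(np.nanmean(eff[m])) if valid.any() else float("nan")
    return eff, mean


def run_fret(sample: FretChannels,
             donor_ref: Optional[FretChannels] = None,
             acceptor_ref: Optional[FretChannels] = None,
             bt: Optional[BleedThrough] = None,
             calibration_method: str = "mean_ratio") -> FretResult:
    """Complete pixel-per-pixel FRET analysis of one sample triplet.

    Background-subtracts all channels, calibrates df/af from the
    reference triplets (unless ``bt`` supplies pre-calibrated factors),
    computes cFRET and the efficiency map over a signal mask (triangle
    threshold on DONOR OR ACCEPTOR).
    """
    if bt is None:
        if donor_ref is None or acceptor_ref is None:
            raise CalibrationError(
                "need donor_ref and acceptor_ref (or explicit bleed-through factors)")
        bt = BleedThrough(
            df=bleed_through_factor(donor_ref, "donor_only", calibration_method),
            af=bleed_through_factor(acceptor_ref, "acceptor_only", calibration_method),
        )
    donor = _background_subtracted(sample.donor)
    raw = _background_subtracted(sample.raw_fret)
    acceptor = _background_subtracted(sample.acceptor)
    corrected = corrected_fret(FretChannels(donor, raw, acceptor), bt)
    mask = BinaryMask(_signal_mask(donor) | _signal_mask(acceptor), "fret_signal")
    eff, mean = fret_efficiency(np.asarray(donor.pixels), corrected, mask)
    return FretResult(cfret=corrected, efficiency=eff, mean_efficiency=mean,
                      analysis_mask=mask, bleed_through=bt)
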