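"""The combined colocalization pipeline.

Runs preprocessing, the intensity-correlation suite, and object
recognition on a channel pair, then weights the intensity coefficients
by the object colocalization area fraction to give the object-corrected
Pearson coefficient (and corrected M1/M2/ICQ).  Batch mode processes a
whole folder, isolating per-pair failures as flagged rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from . import intensity_corr, object_coloc, preprocess
from .errors import DegenerateChannelError, DegenerateHistogramError, ObjcolocError
from .io_formats import ImagePair
from .intensity_corr import IntensityCorrelationResult
from .object_coloc import BinaryMask, ObjectColocStats
from .preprocess import PreprocessReport

#: fixed CSV schema of a batch run
RESULT_COLUMNS = (
    "source_id", "pearson_r", "pearson_r_thresholded", "spearman_rho",
    "m1_zero", "m2_zero", "m1_auto", "m2_auto", "icq",
    "threshold_a", "threshold_b", "regression_slope", "regression_intercept",
    "below_threshold_r",
    "count_a", "count_b", "count_combined", "count_coloc",
    "area_a", "area_b", "area_combined", "area_coloc", "fraction",
    "corrected_pearson", "corrected_m1", "corrected_m2", "corrected_icq",
    "flags",
)


@dataclass(frozen=True)
class ColocConfig:
    """Batch configuration.

    ``min_area`` defaults to 25 px, the particle-analysis cut-off used
    throughout; manual thresholds are required iff the manual method is
    selected.
    """

    object_threshold_method: str = "max_entropy"
    manual_threshold_a: Optional[float] = None
    manual_threshold_b: Optional[float] = None
    min_area: int = 25
    histogram_bins: int = 256
    regression_mode: str = "le_zero_else_closest"
    emit_overlays: bool = False

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        manual = self.object_threshold_method == "manual"
        have = self.manual_threshold_a is not None and self.manual_threshold_b is not None
        if manual and not have:
            raise ValueError("manual thresholding requires manual_threshold_a/_b")
        if not manual and (self.manual_threshold_a is not None
                           or self.manual_threshold_b is not None):
            raise ValueError("manual thresholds given but method is not 'manual'")


@dataclass
class ColocResult:
    source_id: str
    correlation: Optional[IntensityCorrelationResult]
    objects: Optional[ObjectColocStats]
    corrected_pearson: float = float("nan")
    corrected_m1: float = float("nan")
    corrected_m2: float = float("nan")
    corrected_icq: float = float("nan")
    preprocess_a: Optional[PreprocessReport] = None
    preprocess_b: Optional[PreprocessReport] = None
    mask_a: Optional[BinaryMask] = None
    mask_b: Optional[BinaryMask] = None
    flags: str = ""
    pair: Optional[ImagePair] = None  # preprocessed pair, for rendering


def object_corrected(coefficient: float, fraction: float) -> float:
    """Weight an intensity coefficient by the colocalization fraction.

    NaN in either operand propagates.
    """
    if math.isnan(coefficient) or math.isnan(fraction):
        return float("nan")
    return coefficient * fraction


def run_pair(pair: ImagePair, config: ColocConfig = ColocConfig()) -> ColocResult:
    """Full analysis of one channel pair.

    Order of operations: background subtraction per channel, intensity
    equalization, intensity-correlation suite, object thresholding and
    watershed per channel, mask combination/intersection, particle
    statistics, corrected coefficients.  Degenerate inputs yield a
    flagged partial result rather than an exception.
    """
    source_id = pair.source_id
    try:
        a, rep_a = preprocess.subtract_background(pair.a)
        b, rep_b = preprocess.subtract_background(pair.b)
        eq, scale_a, scale_b = preprocess.equalize_intensity_range(ImagePair(a, b))
        rep_a = PreprocessReport(rep_a.triangle_threshold, rep_a.background_level, scale_a)
        rep_b = PreprocessReport(rep_b.triangle_threshold, rep_b.background_level, scale_b)
    except (DegenerateHistogramError, DegenerateChannelError) as exc:
        return ColocResult(source_id, None, None, flags=f"degenerate_channel:{exc}")

    corr = intensity_corr.compute_all(eq, bins=config.histogram_bins,
                                      regression_mode=config.regression_mode)

    mask_a = object_coloc.threshold_objects(
        eq.a, config.object_threshold_method, config.manual_threshold_a)
    mask_b = object_coloc.threshold_objects(
        eq.b, config.object_threshold_method, config.manual_threshold_b)
    mask_a = object_coloc.watershed_split(mask_a)
    mask_b = object_coloc.watershed_split(mask_b)
    stats = object_coloc.coloc_stats(mask_a, mask_b, config.min_area)

    flags = []
    if corr.regression.degenerate:
        flags.append("degenerate_threshold_regression")
    if math.isnan(stats.fraction):
        flags.append("empty_combination_mask")

    return ColocResult(
        source_id=source_id,
        correlation=corr,
        objects=stats,
        corrected_pearson=object_corrected(corr.pearson_r, stats.fraction),
        corrected_m1=object_corrected(corr.m1_zero, stats.fraction),
        corrected_m2=object_corrected(corr.m2_zero, stats.fraction),
        corrected_icq=object_corrected(corr.icq, stats.fraction),
        preprocess_a=rep_a, preprocess_b=rep_b,
        mask_a=mask_a, mask_b=mask_b,
        flags=";".join(flags),
        pair=eq,
    )


def result_to_row(result: ColocResult) -> dict:
    """Flatten a :class:`ColocResult` to the fixed CSV schema."""
    nan = float("nan")
    corr = result.correlation
    obj = result.objects
    reg = corr.regression if corr is not None else None
    row = {
        "source_id": result.source_id,
        "pearson_r": corr.pearson_r if corr else nan,
        "pearson_r_thresholded": corr.pearson_r_thresholded if corr else nan,
        "spearman_rho": corr.spearman_rho if corr else nan,
        "m1_zero": corr.m1_zero if corr else nan,
        "m2_zero": corr.m2_zero if corr else nan,
        "m1_auto": corr.m1_auto if corr else nan,
        "m2_auto": corr.m2_auto if corr else nan,
        "icq": corr.icq if corr else nan,
        "threshold_a": reg.threshold_a if reg else nan,
        "threshold_b": reg.threshold_b if reg else nan,
        "regression_slope": reg.slope if reg else nan,
        "regression_intercept": reg.intercept if reg else nan,
        "below_threshold_r": reg.below_threshold_r if reg else nan,
        "count_a": obj.count_a if obj else nan,
        "count_b": obj.count_b if obj else nan,
        "count_combined": obj.count_combined if obj else nan,
        "count_coloc": obj.count_coloc if obj else nan,
        "area_a": obj.area_a if obj else nan,
        "area_b": obj.area_b if obj else nan,
        "area_combined": obj.area_combined if obj else nan,
        "area_coloc": obj.area_coloc if obj else nan,
        "fraction": obj.fraction if obj else nan,
        "corrected_pearson": result.corrected_pearson,
        "corrected_m1": result.corrected_m1,
        "corrected_m2": result.corrected_m2,
        "corrected_icq": result.corrected_icq,
        "flags": result.flags,
    }
    return row


def run_batch(pairs: Sequence[ImagePair],
              config: ColocConfig = ColocConfig()) -> list[dict]:
    """Analyze a sequence of pairs; one result row each, order preserved.

    A pair that fails analysis produces a flagged row with undefined
    coefficients; the batch never aborts.
    """
    rows = []
    for pair in pairs:
        try:
            result = run_pair(pair, config)
        except ObjcolocError as exc:  # defensive: isolate per-pair failures
            result = ColocResult(pair.source_id, None, None,
                                 flags=f"error:{exc}")
        rows.append(result_to_row(result))
    return rows
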