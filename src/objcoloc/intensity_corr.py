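"""Classical pixel-intensity correlation coefficients.

Pearson, Spearman, the Manders split coefficients M1/M2, Li's intensity
correlation quotient (ICQ), the Costes-style bisection threshold
regression, and the two-channel 2D intensity histogram.  These are the
coefficients the combined pipeline later weights by the object
colocalization fraction.

Undefined results (constant channel, zero denominator) are returned as
NaN, never silently as 0: a fabricated zero would read as "no
colocalization".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import EmptyScopeError
from .io_formats import ImagePair


@dataclass(frozen=True)
class ThresholdRegression:
    """Outcome of the bisection threshold search along the TLS line."""

    threshold_a: float
    threshold_b: float
    slope: float
    intercept: float
    below_threshold_r: float
    degenerate: bool = False


@dataclass(frozen=True)
class IntensityCorrelationResult:
    pearson_r: float
    pearson_r_thresholded: float
    spearman_rho: float
    m1_zero: float
    m2_zero: float
    m1_auto: float
    m2_auto: float
    icq: float
    regression: ThresholdRegression
    histogram: np.ndarray
    histogram_bins: int


def _in_scope(pair: ImagePair, mask: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(pair.a.pixels, dtype=np.float64)
    b = np.asarray(pair.b.pixels, dtype=np.float64)
    if mask is None:
        return a.ravel(), b.ravel()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyScopeError("analysis mask selects no pixels")
    return a[mask], b[mask]


def pearson(pair: ImagePair, mask: Optional[np.ndarray] = None) -> float:
    """Product-moment correlation of the two channels' in-scope pixels.

    Returns NaN when either channel is constant in scope.
    """
    a, b = _in_scope(pair, mask)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def spearman(pair: ImagePair, mask: Optional[np.ndarray] = None) -> float:
    """Rank correlation (Pearson of mid-ranks; ties get average rank)."""
    a, b = _in_scope(pair, mask)
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def manders(pair: ImagePair, threshold_a: float = 0.0,
            threshold_b: float = 0.0) -> tuple[float, float]:
    """Manders split coefficients.

    M1 is the fraction of channel-A intensity residing in pixels where
    channel B exceeds ``threshold_b`` (denominator: total intensity over
    pixels with a > 0); M2 is symmetric.  A zero denominator yields NaN.
    """
    a = np.asarray(pair.a.pixels, dtype=np.float64).ravel()
    b = np.asarray(pair.b.pixels, dtype=np.float64).ravel()
    denom1 = a[a > 0].sum()
    denom2 = b[b > 0].sum()
    m1 = a[b > threshold_b].sum() / denom1 if denom1 > 0 else float("nan")
    m2 = b[a > threshold_a].sum() / denom2 if denom2 > 0 else float("nan")
    return float(m1), float(m2)


def li_icq(pair: ImagePair, mask: Optional[np.ndarray] = None) -> float:
    """Li's intensity correlation quotient.

    Fraction of in-scope pixels whose deviation product
    (a_i - mean_a)(b_i - mean_b) is strictly positive, minus 0.5.
    Zero products count as non-positive.  Range [-0.5, 0.5].
    """
    a, b = _in_scope(pair, mask)
    if a.size < 2:
        raise EmptyScopeError("ICQ needs at least 2 in-scope pixels")
    prod = (a - a.mean()) * (b - b.mean())
    return float((prod > 0).sum() / prod.size - 0.5)


def orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Total-least-squares (orthogonal) line b = slope*a + intercept."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    sxx = a.var()
    syy = b.var()
    sxy = ((a - a.mean()) * (b - b.mean())).mean()
    if sxy == 0:
        slope = 0.0 if syy <= sxx else np.inf
    else:
        slope = (syy - sxx + np.hypot(syy - sxx, 2 * sxy)) / (2 * sxy)
    intercept = b.mean() - slope * a.mean()
    return float(slope), float(intercept)


def _below_r(a: np.ndarray, b: np.ndarray, ta: float, tb: float
             ) -> tuple[float, int]:
    """Pearson r (and n) of the strictly-below-both-thresholds population.

    NaN when fewer than 2 pixels remain or either channel is constant
    in the below population.
    """
    sel = (a < ta) & (b < tb)
    n = int(sel.sum())
    if n < 2:
        return float("nan"), n
    aa, bb = a[sel], b[sel]
    if aa.std() == 0 or bb.std() == 0:
        return float("nan"), n
    return float(np.corrcoef(aa, bb)[0, 1]), n


def _r_is_uncorrelated(r: float, n: int) -> bool:
    """Sign test with a sampling allowance: a finite sub-population of
    genuinely uncorrelated pixels has r fluctuating ~ 1/sqrt(n), so
    "r <= 0" is accepted up to three standard errors of r (one-sided
    false-descent probability ~1% over a whole bisection search)."""
    if not np.isfinite(r):
        return False
    se = 1.0 / np.sqrt(max(n - 3, 1))
    # a population too small for 3*SE to resolve sign cannot be certified
    return 3.0 * se < 1.0 and r <= 3.0 * se


def bisection_threshold_regression(pair: ImagePair,
                                   mode: str = "le_zero_else_closest"
                                   ) -> ThresholdRegression:
    """Automatic channel thresholds along the inter-channel TLS line.

    Fits the orthogonal regression b = slope*a + intercept over all
    pixels, then bisection-searches threshold_a (with
    threshold_b = slope*threshold_a + intercept) for the largest
    threshold whose strictly-below-both population has Pearson r <= 0
    (accepted up to two standard errors of r, since a finite uncorrelated
    population fluctuates ~ 1/sqrt(n)).  The search stops when the
    interval shrinks below one intensity level.

    ``mode`` selects the acceptance rule when no threshold achieves
    r <= 0: ``"le_zero_else_closest"`` (default) falls back to the
    candidate minimizing \\|r\\| over a dense scan; ``"closest"`` uses that
    scan directly.  If the below population is degenerate (fewer than 2
    pixels, or perfectly correlated at every candidate), the result is
    flagged and the thresholds fall to the channel minima.
    """
    if mode not in ("le_zero_else_closest", "closest"):
        raise ValueError(f"unknown mode {mode!r}")
    a = np.asarray(pair.a.pixels, dtype=np.float64).ravel()
    b = np.asarray(pair.b.pixels, dtype=np.float64).ravel()
    slope, intercept = orthogonal_regression(a, b)

    def degenerate() -> ThresholdRegression:
        ta = float(a.min())
        return ThresholdRegression(ta, slope * ta + intercept, slope, intercept,
                                   float("nan"), degenerate=True)

    if a.std() == 0 or b.std() == 0 or not np.isfinite(slope):
        return degenerate()

    lo, hi = float(a.min()), float(a.max())

    def closest_scan() -> ThresholdRegression:
        candidates = np.linspace(lo, hi, 512)
        best_t, best_r = None, np.inf
        for t in candidates:
            r, _ = _below_r(a, b, t, slope * t + intercept)
            if np.isfinite(r) and abs(r) < abs(best_r):
                best_t, best_r = t, r
        if best_t is None or abs(best_r) > 1 - 1e-9:
            # every candidate population is absent or perfectly correlated
            return degenerate()
        return ThresholdRegression(float(best_t), float(slope * best_t + intercept),
                                   slope, intercept, float(best_r))

    if mode == "closest":
        return closest_scan()

    # bisection for the largest threshold whose below population is
    # uncorrelated; correlated or undefined pushes the interval down
    found = None
    r_hi, n_hi = _below_r(a, b, hi, slope * hi + intercept)
    if _r_is_uncorrelated(r_hi, n_hi):
        found = hi
    else:
        blo, bhi = lo, hi
        while bhi - blo >= 1.0:
            mid = 0.5 * (blo + bhi)
            r, n = _below_r(a, b, mid, slope * mid + intercept)
            if _r_is_uncorrelated(r, n):
                blo = mid
                found = mid
            else:
                bhi = mid
    if found is None:
        return closest_scan()
    r, _ = _below_r(a, b, found, slope * found + intercept)
    return ThresholdRegression(float(found), float(slope * found + intercept),
                               slope, intercept, float(r))


def histogram2d(pair: ImagePair, bins: int = 256) -> np.ndarray:
    """Joint intensity histogram with equal-width bins over the full
    bit-depth range of each channel.  ``out[i, j]`` counts pixels in
    a-bin i and b-bin j; the grand total equals the pixel count."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    a = np.asarray(pair.a.pixels, dtype=np.float64).ravel()
    b = np.asarray(pair.b.pixels, dtype=np.float64).ravel()
    counts, _, _ = np.histogram2d(
        a, b, bins=bins,
        range=[[0, pair.a.max_value], [0, pair.b.max_value]],
    )
    return counts.astype(np.int64)


def compute_all(pair: ImagePair, bins: int = 256,
                regression_mode: str = "le_zero_else_closest"
                ) -> IntensityCorrelationResult:
    """The full intensity-correlation suite on one (preprocessed) pair."""
    reg = bisection_threshold_regression(pair, mode=regression_mode)
    m1_zero, m2_zero = manders(pair, 0.0, 0.0)
    if reg.degenerate:
        m1_auto = m2_auto = p_thr = float("nan")
    else:
        m1_auto, m2_auto = manders(pair, reg.threshold_a, reg.threshold_b)
        a = np.asarray(pair.a.pixels, dtype=np.float64)
        b = np.asarray(pair.b.pixels, dtype=np.float64)
        above = (a > reg.threshold_a) | (b > reg.threshold_b)
        try:
            p_thr = pearson(pair, above)
        except EmptyScopeError:
            p_thr = float("nan")
    return IntensityCorrelationResult(
        pearson_r=pearson(pair),
        pearson_r_thresholded=p_thr,
        spearman_rho=spearman(pair),
        m1_zero=m1_zero, m2_zero=m2_zero,
        m1_auto=m1_auto, m2_auto=m2_auto,
        icq=li_icq(pair),
        regression=reg,
        histogram=histogram2d(pair, bins),
        histogram_bins=bins,
    )
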