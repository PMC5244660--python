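"""Run summaries and figures.

Per-group coefficient tables (mean and standard error across images) and
the rendered outputs the batch pipeline can emit: the log-scaled 2D
intensity histogram with the regression line, and channel overlays with
combination / colocalization outlines.
"""

from __future__ import annotations

import os
import warnings
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import LogNorm
from skimage.segmentation import find_boundaries

from .combined_pipeline import ColocResult
from .errors import ValidationError
from .intensity_corr import IntensityCorrelationResult


def summarize(rows: Sequence[dict], group_key: str) -> pd.DataFrame:
    """Mean and standard error of the mean per group per numeric column.

    Rows with a nonempty ``flags`` entry are excluded; undefined (NaN)
    cells are dropped per column with the per-cell n reported.  SEM uses
    the n-1 standard deviation and is NaN for n = 1.
    """
    if not rows:
        warnings.warn("no rows to summarize")
        return pd.DataFrame()
    df = pd.DataFrame(list(rows))
    if group_key not in df.columns:
        raise ValidationError(f"unknown group column {group_key!r}")
    if "flags" in df.columns:
        df = df[(df["flags"].isna()) | (df["flags"] == "")]
    if df.empty:
        warnings.warn("all rows flagged; empty summary")
        return pd.DataFrame()
    numeric = df.select_dtypes(include=[np.number]).columns
    records = []
    for group, sub in df.groupby(group_key, sort=True):
        rec: dict = {group_key: group}
        for col in numeric:
            vals = sub[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            rec[f"{col}_mean"] = vals.mean() if n else float("nan")
            rec[f"{col}_sem"] = (vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            rec[f"{col}_n"] = n
        records.append(rec)
    return pd.DataFrame(records)


def render_histogram(result: IntensityCorrelationResult,
                     path: os.PathLike | str,
                     fraction: Optional[float] = None,
                     max_intensity: int = 4095,
                     role_a: str = "channel A", role_b: str = "channel B") -> None:
    """PNG of the 2D intensity histogram, log-scaled counts, with the
    threshold-regression line overlaid and the Pearson coefficient (and,
    when given, the object colocalization fraction) annotated.

    ``max_intensity`` is the full-range upper bound of both axes (the
    pair's ``2**bit_depth - 1``), used to place the regression line.
    """
    hist = np.asarray(result.histogram, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    masked = np.ma.masked_equal(hist.T, 0)
    ax.imshow(masked, origin="lower", norm=LogNorm(vmin=1), cmap="viridis",
              extent=(0, max_intensity, 0, max_intensity), aspect="auto")
    reg = result.regression
    if np.isfinite(reg.slope) and not reg.degenerate:
        x = np.linspace(0, max_intensity, 64)
        y = reg.slope * x + reg.intercept
        keep = (y >= 0) & (y <= max_intensity)
        ax.plot(x[keep], y[keep], "w--", lw=1)
    text = f"Pearson r = {result.pearson_r:.3f}"
    if fraction is not None and np.isfinite(fraction):
        text += f"\ncoloc fraction = {100 * fraction:.1f}%"
    ax.text(0.03, 0.97, text, transform=ax.transAxes, va="top",
            color="white", fontsize=9)
    ax.set_xlabel(f"{role_a} intensity")
    ax.set_ylabel(f"{role_b} intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_overlay(result: ColocResult, path: os.PathLike | str) -> None:
    """PNG of the merged channels with the combination mask outlined in
    blue and colocalizing objects outlined in white."""
    if result.pair is None or result.mask_a is None or result.mask_b is None:
        raise ValidationError("result carries no image data to render")
    a = np.asarray(result.pair.a.pixels, dtype=float)
    b = np.asarray(result.pair.b.pixels, dtype=float)
    top = max(a.max(), b.max(), 1.0)
    rgb = np.zeros(a.shape + (3,))
    rgb[..., 1] = a / top   # channel A in green
    rgb[..., 0] = b / top   # channel B in red
    comb = result.mask_a.pixels | result.mask_b.pixels
    coloc = result.mask_a.pixels & result.mask_b.pixels
    rgb[find_boundaries(comb, mode="outer")] = (0.2, 0.4, 1.0)
    rgb[find_boundaries(coloc, mode="outer")] = (1.0, 1.0, 1.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.clip(rgb, 0, 1))
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
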