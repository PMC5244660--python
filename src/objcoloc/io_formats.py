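"""Image and table I/O.

Reads single-plane grayscale TIFF channels, pairs them by filename
convention for batch analysis, and writes result tables as CSV.  All
downstream modules consume only the :class:`ChannelImage` /
:class:`ImagePair` containers defined here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, PairingError, UnsupportedLayoutError, ValidationError

#: channel roles understood by the pipelines
ROLES = ("channel_a", "channel_b", "donor", "raw_fret", "acceptor")

#: value written to CSV for undefined results (empty cell)
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ChannelImage:
    """One single-plane grayscale intensity image.

    ``pixels`` is a 2D array of nonnegative intensities in
    ``[0, 2**bit_depth - 1]``.  Pixels are integer-valued for acquired
    data; float arrays are permitted for computed intermediates (e.g.
    noise-free synthetic calibration images) but obey the same range.
    Coordinates are 0-based row-major (axis 0 = row = y).
    """

    pixels: np.ndarray
    bit_depth: int
    role: str
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(
                f"{self.source_id or 'image'}: expected a 2D single-plane image, "
                f"got shape {px.shape}"
            )
        if self.bit_depth not in (8, 12, 16):
            raise ValidationError(f"unsupported bit depth {self.bit_depth}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown channel role {self.role!r}")
        if px.min() < 0:
            raise ValidationError(f"{self.source_id or 'image'}: negative intensities")
        if px.max() > self.max_value:
            raise ValidationError(
                f"{self.source_id or 'image'}: intensity {px.max()} exceeds "
                f"{self.bit_depth}-bit maximum {self.max_value}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        return ChannelImage(pixels, self.bit_depth, self.role, self.source_id)


@dataclass(frozen=True)
class ImagePair:
    """Two dimension-matched channels of one field of view."""

    a: ChannelImage
    b: ChannelImage

    def __post_init__(self) -> None:
        if self.a.shape != self.b.shape:
            raise PairingError(
                f"channel dimensions differ: {self.a.source_id} is "
                f"{self.a.shape}, {self.b.source_id} is {self.b.shape}"
            )

    @property
    def source_id(self) -> str:
        stem_a = Path(self.a.source_id).stem if self.a.source_id else ""
        return stem_a or self.a.source_id


@dataclass
class PairingReport:
    """Outcome of directory pairing: matched pairs plus leftovers."""

    pairs: list[ImagePair] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)


def read_channel(path: os.PathLike | str, role: str,
                 bit_depth: Optional[int] = None) -> ChannelImage:
    """Read a single-plane grayscale integer TIFF as a :class:`ChannelImage`.

    ``bit_depth`` overrides the container depth; use 12 for 12-bit data
    stored in 16-bit TIFFs (values are then validated against the 12-bit
    range).  Multi-plane and RGB files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises assorted types on bad input
        raise FormatError(f"cannot read {path} as TIFF: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise UnsupportedLayoutError(
            f"{path}: RGB(A) images are not supported; split channels first"
        )
    if arr.ndim != 2:
        raise UnsupportedLayoutError(
            f"{path}: multi-plane image (shape {arr.shape}); only single planes "
            "are supported"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedLayoutError(
            f"{path}: non-integer pixel type {arr.dtype}; expected uint8/uint16"
        )
    if bit_depth is None:
        bit_depth = 8 * arr.dtype.itemsize
        if bit_depth not in (8, 16):
            raise UnsupportedLayoutError(f"{path}: unsupported sample size {bit_depth}")
    return ChannelImage(arr.astype(np.int64), bit_depth, role, source_id=str(path))


def write_channel(image: ChannelImage, path: os.PathLike | str) -> None:
    """Write a :class:`ChannelImage` to an uncompressed grayscale TIFF.

    Integer-valued images go out as uint8/uint16; float-valued computed
    images (e.g. noise-free synthetic channels) as float32.
    """
    px = image.pixels
    if np.issubdtype(px.dtype, np.integer):
        dtype = np.uint8 if image.bit_depth == 8 else np.uint16
        tifffile.imwrite(path, px.astype(dtype))
    else:
        tifffile.imwrite(path, px.astype(np.float32))


def pair_by_suffix(directory: os.PathLike | str, suffix_a: str, suffix_b: str,
                   role_a: str = "channel_a", role_b: str = "channel_b",
                   bit_depth: Optional[int] = None,
                   extension: str = ".tif") -> PairingReport:
    """Pair channel files in ``directory`` by shared stem.

    A file ``<stem><suffix_a><ext>`` is paired with ``<stem><suffix_b><ext>``.
    Pairs are ordered lexicographically by stem; files without a partner are
    listed in ``unmatched`` rather than silently dropped.  A dimension
    mismatch within a pair raises :class:`PairingError` naming both files.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"no such directory: {directory}")
    exts = {extension.lower(), ".tiff"}
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() in exts)
    stems_a = {p.stem[: -len(suffix_a)]: p for p in files if p.stem.endswith(suffix_a)}
    stems_b = {p.stem[: -len(suffix_b)]: p for p in files if p.stem.endswith(suffix_b)}
    report = PairingReport()
    for stem in sorted(set(stems_a) & set(stems_b)):
        a = read_channel(stems_a[stem], role_a, bit_depth)
        b = read_channel(stems_b[stem], role_b, bit_depth)
        if a.shape != b.shape:
            raise PairingError(
                f"dimension mismatch: {stems_a[stem].name} is {a.shape}, "
                f"{stems_b[stem].name} is {b.shape}"
            )
        report.pairs.append(ImagePair(a, b))
    matched = {stems_a[s] for s in stems_a if s in stems_b}
    matched |= {stems_b[s] for s in stems_b if s in stems_a}
    report.unmatched = [p.name for p in files if p not in matched]
    return report


def write_results(rows: Sequence[dict], path: os.PathLike | str,
                  columns: Optional[Sequence[str]] = None) -> None:
    """Write result rows to CSV with a fixed column order.

    All rows must share one schema.  Undefined values (NaN) become empty
    cells; numeric values are written at full precision ("." decimal
    separator, RFC 4180 quoting).
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    for row in rows:
        missing = set(columns) - set(row)
        if missing:
            raise ValidationError(f"result row missing columns: {sorted(missing)}")
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, index=False, float_format="%.17g")
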