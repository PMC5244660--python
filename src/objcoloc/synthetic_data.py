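"""Synthetic two-channel fluorescence scenes with known ground truth.

Emulates single-plane confocal images of transfected cells expressing
organelle markers: punctate mitochondria-like blobs, a reticular ER-like
line network, a diffuse cytosol fill, all confined to a randomly shaped
cell footprint that both channels share.  The shared footprint plus a
diffuse background is what produces false-positive pixel-intensity
correlation between markers that occupy disjoint structures — the effect
the object-corrected coefficient is designed to suppress.

Scenarios
---------
``same_structure``    one blob set imaged in both channels with
                      independent per-object gains (true colocalization)
``mito_vs_er``        punctate blobs (A) vs a disjoint reticular network (B)
``mito_vs_cytosol``   punctate blobs (A) vs diffuse fill of the footprint (B)
``overlap_sweep``     two equal-area disk sets sharing exactly a requested
                      fraction of their union area

FRET triplets are generated from an unquenched donor field D0 with a
known true efficiency E: DONOR = D0*(1-E), sensitized emission S = D0*E,
and rawFRET = S + DONOR*df + ACCEPTOR*af, so that the three-filter
analysis inverts the construction exactly in noise-free mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import draw

from .errors import GenerationError
from .fret import FretChannels
from .io_formats import ChannelImage, ImagePair
from .object_coloc import BinaryMask


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions of one synthetic scene.

    Defaults emulate the acquisition the pipeline targets: 12-bit
    single-plane confocal images, a cell filling most of a 256 x 256
    field, object signal around half the dynamic range, diffuse cellular
    background (out-of-focus light plus unincorporated marker) at 40% of
    the object signal, and photon-limited noise at SNR 10.
    """

    scenario: str = "same_structure"
    image_size: tuple[int, int] = (256, 256)
    n_objects: int = 25
    true_overlap_fraction: Optional[float] = None
    background_level: float = 800.0
    signal_level: float = 2000.0
    noise_model: str = "poisson_gaussian"  # "none" | "poisson_gaussian"
    snr: float = 10.0
    bit_depth: int = 12
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """True object supports and scene parameters, for recovery tests."""

    mask_a: BinaryMask
    mask_b: BinaryMask
    true_fraction: float
    true_df: Optional[float] = None
    true_af: Optional[float] = None
    true_efficiency: Optional[float] = None


# --------------------------------------------------------------------------
# geometry primitives

def _cell_footprint(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Random smooth closed cell outline: a low-order Fourier perturbation
    of a disk covering most of the field."""
    rows, cols = shape
    cy, cx = rows / 2, cols / 2
    r0 = 0.40 * min(rows, cols)
    amps = rng.uniform(0.02, 0.08, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2(yy - cy, xx - cx)
    radius = np.hypot(yy - cy, xx - cx)
    boundary = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                               for k, (a, p) in enumerate(zip(amps, phases))))
    return radius <= boundary


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  lo: float, hi: float) -> np.ndarray:
    """Low-frequency multiplicative modulation in [lo, hi]."""
    noise = rng.normal(size=shape)
    field = ndi.gaussian_filter(noise, sigma=min(shape) / 8)
    fmin, fmax = field.min(), field.max()
    if fmax == fmin:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (field - fmin) / (fmax - fmin)


def _place_centers(footprint: np.ndarray, n: int, min_dist: float,
                   rng: np.random.Generator, margin: float = 0.82,
                   max_tries: int = 20000,
                   floor: float = 0.0) -> list[tuple[int, int]]:
    """Rejection-sample integer centers inside the shrunken footprint with a
    minimum pairwise distance.

    If the footprint is too small to hold ``n`` centers at the requested
    spacing, the spacing is relaxed deterministically in 10% steps (down
    to 60%, never below ``floor``) before the request is declared
    infeasible.  ``floor`` guards constructions that need hard
    separation, e.g. non-touching disks of known area.
    """
    rows, cols = footprint.shape
    cy, cx = rows / 2, cols / 2
    dists = []
    for relax in (1.0, 0.9, 0.8, 0.7, 0.6):
        d = max(min_dist * relax, floor)
        if d not in dists:
            dists.append(d)
    for dist in dists:
        centers: list[tuple[int, int]] = []
        for _ in range(max_tries):
            if len(centers) == n:
                return centers
            y = int(rng.integers(0, rows))
            x = int(rng.integers(0, cols))
            if not footprint[y, x]:
                continue
            # shrink toward the centroid so objects do not cross the cell edge
            yy = int(round(cy + margin * (y - cy)))
            xx = int(round(cx + margin * (x - cx)))
            if not footprint[yy, xx]:
                continue
            if any((yy - py) ** 2 + (xx - px) ** 2 < dist**2 for py, px in centers):
                continue
            centers.append((yy, xx))
    raise GenerationError(
        f"could not place {n} objects with spacing {min_dist} in the footprint")


def _render_blobs(shape: tuple[int, int], centers: list[tuple[int, int]],
                  rng: np.random.Generator, r_minor: tuple[float, float],
                  r_major: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Hard-edged random ellipses; returns (support mask, per-pixel gain)."""
    mask = np.zeros(shape, dtype=bool)
    gain = np.zeros(shape, dtype=np.float64)
    for (y, x) in centers:
        a = rng.uniform(*r_major)
        b = rng.uniform(*r_minor)
        rot = rng.uniform(0, np.pi)
        g = rng.uniform(0.7, 1.3)
        rr, cc = draw.ellipse(y, x, a, b, shape=shape, rotation=rot)
        mask[rr, cc] = True
        gain[rr, cc] = g
    return mask, gain


def _render_network(footprint: np.ndarray, rng: np.random.Generator,
                    n_segments: int = 60) -> np.ndarray:
    """Reticular ER-like line network: random walks inside the footprint,
    dilated to a few pixels width."""
    rows, cols = footprint.shape
    skel = np.zeros_like(footprint)
    inside = np.argwhere(footprint)
    for _ in range(4):  # a few independent branches
        y, x = inside[rng.integers(len(inside))]
        for _ in range(n_segments // 4):
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(12, 28)
            y2 = int(np.clip(y + step * np.sin(ang), 0, rows - 1))
            x2 = int(np.clip(x + step * np.cos(ang), 0, cols - 1))
            rr, cc = draw.line(int(y), int(x), y2, x2)
            keep = footprint[rr, cc]
            skel[rr[keep], cc[keep]] = True
            if footprint[y2, x2]:
                y, x = y2, x2
    return ndi.binary_dilation(skel, structure=np.ones((3, 3), dtype=bool))


def _apply_noise_and_quantize(image: np.ndarray, spec: SceneSpec,
                              rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise scaled to the target SNR at the object signal
    level, plus Gaussian read noise (sigma = 2 levels), then integer
    quantization and clipping to the bit-depth range."""
    max_value = 2**spec.bit_depth - 1
    if spec.noise_model == "none":
        return np.clip(image, 0, max_value)
    if spec.noise_model != "poisson_gaussian":
        raise GenerationError(f"unknown noise model {spec.noise_model!r}")
    # photons-per-level calibration: SNR = sqrt(N) at the object signal level
    scale = spec.snr**2 / spec.signal_level
    noisy = rng.poisson(np.maximum(image, 0) * scale) / scale
    noisy = noisy + rng.normal(0.0, 2.0, size=image.shape)
    return np.clip(np.rint(noisy), 0, max_value).astype(np.int64)


def _to_channel(image: np.ndarray, spec: SceneSpec, role: str,
                source_id: str) -> ChannelImage:
    return ChannelImage(image, spec.bit_depth, role, source_id)


# --------------------------------------------------------------------------
# overlap-sweep construction

def _sweep_counts(fraction: float) -> tuple[int, int]:
    """Integer (n_shared, n_exclusive_per_channel) disk counts realizing
    shared/(shared + 2*exclusive) closest to the requested fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise GenerationError("true_overlap_fraction must lie in [0, 1]")
    if fraction == 1.0:
        return 16, 0
    best = None
    for m in range(1, 13):
        k = round(2 * fraction * m / (1 - fraction)) if fraction < 1 else 0
        if k + 2 * m > 30:
            continue
        achieved = k / (k + 2 * m)
        err = abs(achieved - fraction)
        if best is None or err < best[0]:
            best = (err, k, m)
    if best is None or best[0] > 0.01:
        raise GenerationError(
            f"cannot realize overlap fraction {fraction} within tolerance 0.01")
    return best[1], best[2]


# --------------------------------------------------------------------------
# public generators

def generate_pair(spec: SceneSpec) -> tuple[ImagePair, GroundTruth]:
    """Render one two-channel scene and its ground truth.

    Identical specs give bit-identical output: all randomness flows from
    ``spec.seed`` through one generator instance.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size
    footprint = _cell_footprint(shape, rng)
    # diffuse background shared by both channels, smoothly modulated the
    # way cell thickness and out-of-focus light modulate a confocal slice;
    # this shared component is what drives false-positive correlation
    bg = spec.background_level * footprint * _smooth_field(shape, rng, 0.6, 1.4)

    if spec.scenario == "same_structure":
        centers = _place_centers(footprint, spec.n_objects, 14.0, rng)
        mask, _ = _render_blobs(shape, centers, rng, (3.5, 6.0), (4.5, 8.0))
        gain_a = np.where(mask, 0.0, 0.0)
        gain_b = gain_a.copy()
        # independent per-object gains in the two channels
        labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
        ga = rng.uniform(0.7, 1.3, size=n + 1)
        gb = rng.uniform(0.7, 1.3, size=n + 1)
        ga[0] = gb[0] = 0.0
        gain_a = ga[labels]
        gain_b = gb[labels]
        mask_a = mask_b = mask
    elif spec.scenario in ("mito_vs_er", "mito_vs_cytosol"):
        centers = _place_centers(footprint, spec.n_objects, 14.0, rng)
        mask_a, gain_a = _render_blobs(shape, centers, rng, (2.5, 4.5), (3.0, 5.5))
        if spec.scenario == "mito_vs_er":
            net = _render_network(footprint, rng)
            net &= ~mask_a  # true structures are disjoint
            mask_b = net
            gain_b = net * _smooth_field(shape, rng, 0.8, 1.2)
        else:
            mask_b = footprint
            gain_b = 0.45 * footprint * _smooth_field(shape, rng, 0.85, 1.15)
    elif spec.scenario == "overlap_sweep":
        if spec.true_overlap_fraction is None:
            raise GenerationError("overlap_sweep requires true_overlap_fraction")
        k, m = _sweep_counts(spec.true_overlap_fraction)
        radius = 6
        centers = _place_centers(footprint, k + 2 * m, 2 * radius + 5.0, rng,
                                 floor=2 * radius + 2.0)
        mask_a = np.zeros(shape, dtype=bool)
        mask_b = np.zeros(shape, dtype=bool)
        for i, (y, x) in enumerate(centers):
            rr, cc = draw.disk((y, x), radius, shape=shape)
            if i < k:
                mask_a[rr, cc] = True
                mask_b[rr, cc] = True
            elif i < k + m:
                mask_a[rr, cc] = True
            else:
                mask_b[rr, cc] = True
        gain_a = mask_a * rng.uniform(0.85, 1.15)
        gain_b = mask_b * rng.uniform(0.85, 1.15)
    else:
        raise GenerationError(f"unknown scenario {spec.scenario!r}")

    img_a = bg + spec.signal_level * gain_a
    img_b = bg + spec.signal_level * gain_b
    img_a = _apply_noise_and_quantize(img_a, spec, rng)
    img_b = _apply_noise_and_quantize(img_b, spec, rng)

    union = int((mask_a | mask_b).sum())
    inter = int((mask_a & mask_b).sum())
    truth = GroundTruth(
        mask_a=BinaryMask(mask_a, "channel_a"),
        mask_b=BinaryMask(mask_b, "channel_b"),
        true_fraction=(inter / union) if union else float("nan"),
    )
    sid = f"{spec.scenario}_seed{spec.seed}"
    pair = ImagePair(
        _to_channel(img_a, spec, "channel_a", sid + "_A"),
        _to_channel(img_b, spec, "channel_b", sid + "_B"),
    )
    return pair, truth


def _donor_field(spec: SceneSpec, footprint: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Unquenched donor image D0: diffuse expression over the footprint
    with smooth cell-to-cell intensity modulation."""
    return spec.signal_level * footprint * _smooth_field(spec.image_size, rng, 0.7, 1.3)


def generate_fret_triplet(spec: SceneSpec, true_df: float, true_af: float,
                          true_efficiency: float,
                          acceptor_mode: Optional[str] = None
                          ) -> tuple[FretChannels, GroundTruth]:
    """Render a DONOR / rawFRET / ACCEPTOR triplet with known parameters.

    ``acceptor_mode`` is ``"fusion"`` (acceptor stoichiometric with the
    donor, as for a covalent donor-acceptor chimera) or
    ``"coexpression"`` (independent acceptor expression); by default
    fusion when the true efficiency is positive, co-expression otherwise.
    In noise-free mode the channels are kept real-valued so that the
    three-filter analysis inverts the construction exactly.
    """
    if not 0.0 <= true_efficiency < 1.0:
        raise GenerationError("true_efficiency must lie in [0, 1)")
    if acceptor_mode is None:
        acceptor_mode = "fusion" if true_efficiency > 0 else "coexpression"
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size
    footprint = _cell_footprint(shape, rng)
    d0 = _donor_field(spec, footprint, rng)
    donor = d0 * (1.0 - true_efficiency)
    sensitized = d0 * true_efficiency
    if acceptor_mode == "fusion":
        acceptor = d0.copy()
    elif acceptor_mode == "coexpression":
        acceptor = spec.signal_level * footprint * _smooth_field(shape, rng, 0.7, 1.3)
    else:
        raise GenerationError(f"unknown acceptor_mode {acceptor_mode!r}")
    # no separate additive background: diffuse cellular fluorescence is
    # itself fluorophore emission (part of D0 / ACCEPTOR) and therefore
    # already obeys the bleed-through algebra
    raw = sensitized + donor * true_df + acceptor * true_af
    channels = [donor, raw, acceptor]
    if spec.noise_model != "none":
        channels = [_apply_noise_and_quantize(c, spec, rng) for c in channels]
    else:
        max_value = 2**spec.bit_depth - 1
        channels = [np.clip(c, 0, max_value) for c in channels]
    sid = f"fret_{acceptor_mode}_seed{spec.seed}"
    triplet = FretChannels(
        _to_channel(channels[0], spec, "donor", sid + "_D"),
        _to_channel(channels[1], spec, "raw_fret", sid + "_F"),
        _to_channel(channels[2], spec, "acceptor", sid + "_A"),
    )
    truth = GroundTruth(
        mask_a=BinaryMask(footprint, "donor"),
        mask_b=BinaryMask(footprint, "acceptor"),
        true_fraction=1.0,
        true_df=true_df, true_af=true_af, true_efficiency=true_efficiency,
    )
    return triplet, truth


def generate_fret_reference(spec: SceneSpec, kind: str,
                            true_factor: float) -> FretChannels:
    """Single-fluorophore calibration triplet.

    ``donor_only``: DONOR carries the expression pattern, rawFRET is
    exactly ``true_factor`` times it, ACCEPTOR is dark.
    ``acceptor_only`` is symmetric.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_size
    footprint = _cell_footprint(shape, rng)
    signal = spec.signal_level * footprint * _smooth_field(shape, rng, 0.7, 1.3)
    raw = true_factor * signal
    dark = np.zeros(shape)
    if kind == "donor_only":
        channels = [signal, raw, dark]
        roles = ("donor", "raw_fret", "acceptor")
    elif kind == "acceptor_only":
        channels = [dark, raw, signal]
        roles = ("donor", "raw_fret", "acceptor")
    else:
        raise GenerationError(f"unknown reference kind {kind!r}")
    if spec.noise_model != "none":
        channels = [_apply_noise_and_quantize(c, spec, rng) for c in channels]
    else:
        max_value = 2**spec.bit_depth - 1
        channels = [np.clip(c, 0, max_value) for c in channels]
    sid = f"ref_{kind}_seed{spec.seed}"
    return FretChannels(*(
        _to_channel(c, spec, role, f"{sid}_{role}")
        for c, role in zip(channels, roles)
    ))


def generate_threshold_knee_pair(bit_depth: int = 8, knee_fraction: float = 0.5,
                                 slope: float = 0.5, n_pixels: int = 16384,
                                 noise_sd_fraction: float = 0.02,
                                 seed: int = 0) -> tuple[ImagePair, float]:
    """Pair with a correlated subpopulation above a known intensity knee.

    Channel A is uniform over the full range; above the knee, B follows
    ``slope * a`` plus small noise, below it B is independent noise.
    Used to exercise the automatic threshold regression; returns the pair
    and the knee intensity.
    """
    rng = np.random.default_rng(seed)
    max_value = 2**bit_depth - 1
    knee = knee_fraction * max_value
    side = int(math.isqrt(n_pixels))
    a = rng.uniform(0, max_value, size=(side, side))
    sd = noise_sd_fraction * max_value
    b = np.where(
        a > knee,
        slope * a + rng.normal(0, sd, size=a.shape),
        rng.uniform(0, slope * knee, size=a.shape),
    )
    a = np.clip(np.rint(a), 0, max_value).astype(np.int64)
    b = np.clip(np.rint(b), 0, max_value).astype(np.int64)
    pair = ImagePair(
        ChannelImage(a, bit_depth, "channel_a", f"knee_seed{seed}_A"),
        ChannelImage(b, bit_depth, "channel_b", f"knee_seed{seed}_B"),
    )
    return pair, float(knee)
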