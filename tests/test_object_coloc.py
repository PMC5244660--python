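import numpy as np
import pytest
from skimage import draw

from objcoloc import object_coloc as oc
from objcoloc.errors import DegenerateHistogramError, ValidationError
from objcoloc.io_formats import ChannelImage
from objcoloc.object_coloc import BinaryMask


def entropy_oracle(counts):
    """Exhaustive search of the two-class entropy objective."""
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    best_t, best_h = None, -np.inf
    for t in range(len(p) - 1):
        w0, w1 = p[: t + 1].sum(), p[t + 1:].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        q0 = p[: t + 1][p[: t + 1] > 0] / w0
        q1 = p[t + 1:][p[t + 1:] > 0] / w1
        h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if h > best_h:
            best_t, best_h = t, h
    return best_t


@pytest.mark.parametrize("seed", range(6))
def test_max_entropy_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 200, size=256)
    counts[rng.integers(0, 50)] += 2000  # background mode
    assert oc._entropy_threshold_bin(counts) == entropy_oracle(counts)


def test_max_entropy_two_valued_image_selects_bright_class():
    px = np.zeros((10, 10), dtype=np.int64)
    px.flat[:10] = 100
    mask = oc.threshold_objects(ChannelImage(px, 8, "channel_a"), "max_entropy")
    np.testing.assert_array_equal(mask.pixels, px == 100)


def test_default_threshold_symmetric_bimodal():
    rng = np.random.default_rng(0)
    vals = np.concatenate([
        rng.normal(50, 8, size=2000), rng.normal(150, 8, size=2000)
    ]).clip(0, 255).astype(np.int64)
    img = ChannelImage(vals.reshape(40, 100), 8, "channel_a")
    counts, _ = __import__("objcoloc.preprocess", fromlist=["intensity_histogram"]
                           ).intensity_histogram(img)
    t = oc._intermeans_threshold_bin(counts)
    assert t == pytest.approx(100, abs=1)


def test_manual_threshold_is_strict():
    px = np.array([[0, 1], [1, 0]])
    mask = oc.threshold_objects(ChannelImage(px, 8, "channel_a"), "manual",
                                manual_value=0)
    np.testing.assert_array_equal(mask.pixels, px == 1)


def test_threshold_constant_image_is_degenerate():
    img = ChannelImage(np.full((8, 8), 3), 8, "channel_a")
    with pytest.raises(DegenerateHistogramError):
        oc.threshold_objects(img, "max_entropy")
    with pytest.raises(DegenerateHistogramError):
        oc.threshold_objects(img, "default")


# ---------------------------------------------------------------------------
# watershed

def disk_mask(shape, centers, radius):
    m = np.zeros(shape, dtype=bool)
    for c in centers:
        rr, cc = draw.disk(c, radius, shape=shape)
        m[rr, cc] = True
    return BinaryMask(m)


def n_components(mask):
    from scipy import ndimage as ndi
    _, n = ndi.label(mask.pixels, structure=np.ones((3, 3), dtype=bool))
    return n


def test_watershed_single_disk_unchanged():
    m = disk_mask((40, 40), [(20, 20)], 10)
    out = oc.watershed_split(m)
    np.testing.assert_array_equal(out.pixels, m.pixels)


def test_watershed_splits_touching_disks():
    m = disk_mask((50, 70), [(25, 25), (25, 41)], 10)
    assert n_components(m) == 1
    out = oc.watershed_split(m)
    assert n_components(out) == 2
    # foreground never grows
    assert not (out.pixels & ~m.pixels).any()


def test_watershed_empty_mask():
    m = BinaryMask(np.zeros((10, 10), dtype=bool))
    assert not oc.watershed_split(m).pixels.any()


@pytest.mark.parametrize("seed", range(3))
def test_watershed_never_grows_or_merges(seed):
    rng = np.random.default_rng(seed)
    m = BinaryMask(rng.random((64, 64)) > 0.6)
    out = oc.watershed_split(m)
    assert not (out.pixels & ~m.pixels).any()
    assert n_components(out) >= n_components(m)


# ---------------------------------------------------------------------------
# mask algebra

def rect_mask(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return BinaryMask(m)


def test_combine_and_intersect_algebra():
    a = rect_mask((30, 30), 0, 0, 10, 10)   # 100 px
    b = rect_mask((30, 30), 20, 20, 5, 10)  # 50 px, disjoint
    assert oc.combine_masks(a, b).area == 150
    assert oc.intersect_masks(a, b).area == 0
    assert oc.combine_masks(a, a).area == a.area
    sub = rect_mask((30, 30), 0, 0, 5, 10)
    assert np.array_equal(oc.combine_masks(sub, a).pixels, a.pixels)
    c = rect_mask((30, 30), 5, 0, 10, 10)   # overlaps a in 50 px
    assert oc.intersect_masks(a, c).area == 50


def test_mask_dimension_mismatch_raises():
    a = rect_mask((10, 10), 0, 0, 2, 2)
    b = rect_mask((10, 12), 0, 0, 2, 2)
    with pytest.raises(ValidationError):
        oc.combine_masks(a, b)


# ---------------------------------------------------------------------------
# particle analysis

def test_min_area_filter_is_inclusive():
    m = np.zeros((40, 40), dtype=bool)
    m[1:5, 1:7] = True      # 24 px
    m[10:15, 10:15] = True  # 25 px
    m[20:22, 20:33] = True  # 26 px
    objs = oc.analyze_particles(BinaryMask(m), min_area=25)
    assert sorted(a for _, a, _ in objs.objects) == [25, 26]
    assert objs.count == 2
    assert (objs.labels > 0).sum() == 51


def test_analyze_particles_empty_and_conservation(rng):
    assert oc.analyze_particles(BinaryMask(np.zeros((5, 5), dtype=bool))).count == 0
    m = BinaryMask(rng.random((64, 64)) > 0.7)
    objs = oc.analyze_particles(m, min_area=1)
    assert objs.total_area == m.area


def test_coloc_stats_fractions():
    ident = rect_mask((40, 40), 5, 5, 10, 10)
    s = oc.coloc_stats(ident, ident)
    assert s.fraction == 1.0 and s.area_coloc == 100
    a = rect_mask((40, 40), 0, 0, 10, 10)
    b = rect_mask((40, 40), 25, 25, 10, 10)
    assert oc.coloc_stats(a, b).fraction == 0.0
    c = rect_mask((40, 40), 5, 0, 10, 10)  # overlaps a in 50 px
    s = oc.coloc_stats(a, c)
    assert s.fraction == pytest.approx(50 / 150)


def test_coloc_stats_symmetric_and_nested(rng):
    a = BinaryMask(rng.random((64, 64)) > 0.5)
    b = BinaryMask(rng.random((64, 64)) > 0.5)
    assert oc.coloc_stats(a, b, 1).fraction == oc.coloc_stats(b, a, 1).fraction
    sub = BinaryMask(a.pixels & (rng.random((64, 64)) > 0.5))
    s = oc.coloc_stats(sub, a, 1)
    assert s.fraction == pytest.approx(sub.area / a.area)


def test_coloc_stats_empty_combination_is_nan():
    empty = BinaryMask(np.zeros((8, 8), dtype=bool))
    assert np.isnan(oc.coloc_stats(empty, empty).fraction)


def test_fraction_monotone_in_overlap():
    fractions = []
    for shift in [20, 15, 10, 5, 0]:
        a = rect_mask((60, 60), 10, 10, 10, 20)
        b = rect_mask((60, 60), 10, 10 + shift, 10, 20)
        fractions.append(oc.coloc_stats(a, b, 1).fraction)
    assert all(x < y for x, y in zip(fractions, fractions[1:]))
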