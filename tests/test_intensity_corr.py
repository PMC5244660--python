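import math

import numpy as np
import pytest

from conftest import make_pair
from objcoloc import intensity_corr as ic
from objcoloc import synthetic_data as sd
from objcoloc.errors import EmptyScopeError


# ---------------------------------------------------------------------------
# brute-force oracles: naive double loops over pixels, independent of the
# vectorized implementations

def pearson_oracle(a, b):
    n = a.size
    ma = sum(a.flat) / n
    mb = sum(b.flat) / n
    cov = sxx = syy = 0.0
    for x, y in zip(a.flat, b.flat):
        cov += (x - ma) * (y - mb)
        sxx += (x - ma) ** 2
        syy += (y - mb) ** 2
    if sxx == 0 or syy == 0:
        return float("nan")
    return cov / math.sqrt(sxx * syy)


def midrank_oracle(v):
    flat = list(v.flat)
    ranks = []
    for x in flat:
        below = sum(1 for y in flat if y < x)
        ties = sum(1 for y in flat if y == x)
        ranks.append(below + (ties + 1) / 2)
    return np.array(ranks)


def icq_oracle(a, b):
    ma = sum(a.flat) / a.size
    mb = sum(b.flat) / b.size
    pos = sum(1 for x, y in zip(a.flat, b.flat) if (x - ma) * (y - mb) > 0)
    return pos / a.size - 0.5


def manders_oracle(a, b, ta, tb):
    num1 = sum(x for x, y in zip(a.flat, b.flat) if y > tb)
    den1 = sum(x for x in a.flat if x > 0)
    num2 = sum(y for x, y in zip(a.flat, b.flat) if x > ta)
    den2 = sum(y for y in b.flat if y > 0)
    m1 = num1 / den1 if den1 else float("nan")
    m2 = num2 / den2 if den2 else float("nan")
    return m1, m2


@pytest.mark.parametrize("seed", range(10))
def test_coefficients_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    shape = (int(rng.integers(2, 24)), int(rng.integers(2, 24)))
    a = rng.integers(0, 256, size=shape)
    b = rng.integers(0, 256, size=shape)
    pair = make_pair(a, b)
    assert ic.pearson(pair) == pytest.approx(pearson_oracle(a, b), abs=1e-10)
    assert ic.spearman(pair) == pytest.approx(
        pearson_oracle(midrank_oracle(a), midrank_oracle(b)), abs=1e-10)
    assert ic.li_icq(pair) == pytest.approx(icq_oracle(a, b), abs=1e-10)
    m1, m2 = ic.manders(pair)
    o1, o2 = manders_oracle(a, b, 0, 0)
    assert m1 == pytest.approx(o1, abs=1e-10)
    assert m2 == pytest.approx(o2, abs=1e-10)


# ---------------------------------------------------------------------------
# hand-derived examples

def test_pearson_hand_examples():
    assert ic.pearson(make_pair([1, 2, 3, 4], [1, 3, 2, 4])) == pytest.approx(0.8)
    a = np.array([[3, 7], [1, 9]])
    assert ic.pearson(make_pair(a, a)) == pytest.approx(1.0)
    assert ic.pearson(make_pair(a, 255 - a)) == pytest.approx(-1.0)


def test_pearson_constant_channel_is_nan_not_zero():
    assert math.isnan(ic.pearson(make_pair([5, 5, 5, 5], [1, 2, 3, 4])))


def test_pearson_empty_mask_raises():
    pair = make_pair([1, 2, 3, 4], [1, 3, 2, 4])
    with pytest.raises(EmptyScopeError):
        ic.pearson(pair, np.zeros((1, 4), dtype=bool))


def test_spearman_hand_examples():
    a = np.array([1, 2, 3, 4])
    assert ic.spearman(make_pair(a, a**3)) == pytest.approx(1.0)
    assert ic.spearman(make_pair(a, a[::-1].copy())) == pytest.approx(-1.0)
    assert ic.spearman(make_pair([1, 1, 2, 3], [2, 2, 4, 6])) == pytest.approx(1.0)


def test_manders_hand_examples():
    m1, m2 = ic.manders(make_pair([10, 0, 5], [0, 0, 7]))
    assert m1 == pytest.approx(1 / 3)
    assert m2 == pytest.approx(1.0)
    m1, _ = ic.manders(make_pair([10, 0, 5], [1, 2, 3]))
    assert m1 == pytest.approx(1.0)  # b positive everywhere
    m1, m2 = ic.manders(make_pair([10, 0, 0], [0, 0, 7]))
    assert m1 == 0.0 and m2 == 0.0  # disjoint supports


def test_manders_monotone_in_threshold(rng):
    a = rng.integers(0, 256, size=(16, 16))
    b = rng.integers(0, 256, size=(16, 16))
    pair = make_pair(a, b)
    m1s = [ic.manders(pair, 0, tb)[0] for tb in range(0, 250, 25)]
    assert all(x >= y - 1e-12 for x, y in zip(m1s, m1s[1:]))


def test_icq_hand_examples():
    assert ic.li_icq(make_pair([1, 2, 3, 4], [4, 3, 2, 1])) == pytest.approx(-0.5)
    assert ic.li_icq(make_pair([1, 2, 4, 5], [1, 2, 4, 5])) == pytest.approx(0.5)


def test_icq_near_zero_for_independent_noise():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 4096, size=(1000, 1000))
    b = rng.integers(0, 4096, size=(1000, 1000))
    assert abs(ic.li_icq(make_pair(a, b, bit_depth=12))) < 0.005


@pytest.mark.parametrize("seed", range(4))
def test_pearson_spearman_affine_invariance(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 1000, size=(24, 24))
    b = rng.integers(0, 1000, size=(24, 24))
    pair = make_pair(a, b, bit_depth=12)
    scaled = make_pair(2 * a + 50, b, bit_depth=12)
    assert ic.pearson(scaled) == pytest.approx(ic.pearson(pair), abs=0.01)
    assert ic.spearman(scaled) == pytest.approx(ic.spearman(pair), abs=0.01)


# ---------------------------------------------------------------------------
# 2D histogram

def test_histogram2d_constant_pair_single_cell():
    h = ic.histogram2d(make_pair(np.full((4, 4), 7), np.full((4, 4), 200)), bins=4)
    assert h.sum() == 16
    assert (h > 0).sum() == 1


def test_histogram2d_hand_binning():
    # 8-bit, 4 bins of width ~63.75: values 0, 70, 140, 255
    a = np.array([[0, 70], [140, 255]])
    b = np.array([[0, 0], [255, 255]])
    h = ic.histogram2d(make_pair(a, b), bins=4)
    assert h[0, 0] == 1 and h[1, 0] == 1 and h[2, 3] == 1 and h[3, 3] == 1
    assert h.sum() == 4


def test_histogram2d_diagonal_for_identical_channels(rng):
    a = rng.integers(0, 256, size=(64, 64))
    h = ic.histogram2d(make_pair(a, a), bins=32)
    diag_mass = sum(h[i, j] for i in range(32) for j in range(32) if abs(i - j) <= 2)
    assert diag_mass / h.sum() >= 0.95


# ---------------------------------------------------------------------------
# bisection threshold regression

def test_regression_identical_channels_is_degenerate(rng):
    a = rng.integers(0, 256, size=(32, 32))
    reg = ic.bisection_threshold_regression(make_pair(a, a.copy()))
    assert reg.degenerate
    assert reg.threshold_a == a.min()


def test_regression_slope_recovery(rng):
    a = rng.integers(0, 1900, size=(64, 64))
    b = (2.0 * a + 100 + rng.normal(0, 20, size=a.shape)).clip(0, 4095)
    pair = make_pair(a, b.astype(np.int64), bit_depth=12)
    reg = ic.bisection_threshold_regression(pair)
    assert reg.slope == pytest.approx(2.0, abs=0.02)
    assert reg.intercept == pytest.approx(100, abs=20)


@pytest.mark.parametrize("seed", range(5))
def test_regression_recovers_intensity_knee(seed):
    pair, knee = sd.generate_threshold_knee_pair(bit_depth=8, seed=seed)
    reg = ic.bisection_threshold_regression(pair)
    assert not reg.degenerate
    assert reg.threshold_a == pytest.approx(knee, rel=0.05)
    assert abs(reg.below_threshold_r) <= 0.05
    # thresholds sit on the regression line
    assert reg.threshold_b == pytest.approx(
        reg.slope * reg.threshold_a + reg.intercept, abs=1.0)


def test_regression_closest_mode_runs(rng):
    a = rng.integers(0, 256, size=(32, 32))
    b = rng.integers(0, 256, size=(32, 32))
    reg = ic.bisection_threshold_regression(make_pair(a, b), mode="closest")
    assert not reg.degenerate
    assert abs(reg.below_threshold_r) < 0.2
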