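"""Unevenness pipeline: median profile, LOWESS, extrema, peak geometry, U_E."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from covqc.unevenness import (
    MedianProfile,
    Peak,
    SmoothedProfile,
    detect_extrema,
    median_profile,
    peak_geometry,
    smooth_profile,
    ue_for_matrix,
    ue_for_region,
    ue_score,
)

from conftest import make_catalog, make_matrix


def reference_lowess(y, span):
    """Naive reference LOWESS with the same pinned window/weight definitions:
    k = max(ceil(span*n), 4) nearest positions (ties toward lower index),
    tricube weights, weighted least-squares line, no robustness iterations.
    Written point by point with explicit solver calls, independent of the
    package's vectorised path."""
    y = [float(v) for v in y]
    n = len(y)
    k = min(max(math.ceil(span * n), 4), n)
    out = []
    for i in range(n):
        # pick k nearest indices, ties toward the lower index
        order = sorted(range(n), key=lambda j: (abs(j - i), j))
        idx = sorted(order[:k])
        d = [abs(j - i) for j in idx]
        dmax = max(d)
        if dmax == 0:
            out.append(y[i])
            continue
        w = [(1 - (dj / dmax) ** 3) ** 3 for dj in d]
        A = np.array([[wj, wj * j] for wj, j in zip(w, idx)])
        # weighted normal equations for intercept a and slope b
        W = np.diag(w)
        X = np.array([[1.0, j] for j in idx])
        yv = np.array([y[j] for j in idx])
        XtWX = X.T @ W @ X
        XtWy = X.T @ W @ yv
        if abs(np.linalg.det(XtWX)) < 1e-9:
            out.append(float(np.average(yv, weights=w)))
        else:
            a, b = np.linalg.solve(XtWX, XtWy)
            out.append(float(a + b * i))
    return out


def brute_force_extrema(values):
    """Exhaustive neighbour scan oracle for hill-climbing extrema.

    For each position, look left and right past any plateau to the first
    differing values; classify peak/trough; report plateau centres once;
    a run at a boundary classifies by its one interior flank but an apex
    on position 0 or n-1 itself never counts as a peak; then keep a
    single lowest trough (leftmost on ties) between consecutive peaks.
    """
    v = list(values)
    n = len(v)
    if n < 3:
        return [], []
    peaks, troughs = [], []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        center = (i + j) // 2
        left = v[i - 1] if i > 0 else None
        right = v[j + 1] if j < n - 1 else None
        flanks = [f for f in (left, right) if f is not None]
        if flanks:
            if all(f < v[i] for f in flanks) and center not in (0, n - 1):
                peaks.append(center)
            elif all(f > v[i] for f in flanks):
                troughs.append(center)
        i = j + 1
    if len(peaks) > 1:
        kept = [t for t in troughs if t < peaks[0] or t > peaks[-1]]
        for a, b in zip(peaks, peaks[1:]):
            between = [t for t in troughs if a < t < b]
            if between:
                kept.append(min(between, key=lambda t: (v[t], t)))
        troughs = sorted(kept)
    return peaks, troughs


class TestMedianProfile:
    def test_single_sample_identity(self):
        d = np.array([[3, 9, 1, 4]])
        assert median_profile(d).values.tolist() == [3, 9, 1, 4]

    def test_order_statistic_and_midpoint(self):
        d = np.array([[5], [10], [100]])
        assert median_profile(d).values.tolist() == [10]
        d = np.array([[0], [10], [20], [30]])
        assert median_profile(d).values.tolist() == [15]


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        p = MedianProfile("r", np.full(200, 20.0))
        assert smooth_profile(p).values.tolist() == [20.0] * 200

    @pytest.mark.parametrize("span", [0.03, 0.1, 0.5])
    def test_linear_profile_preserved(self, span):
        y = 2.0 * np.arange(150) + 5
        out = smooth_profile(MedianProfile("r", y), span).values
        assert np.allclose(out, y, atol=1e-8)

    def test_matches_reference_on_noisy_sinusoid(self):
        rng = np.random.default_rng(42)
        x = np.arange(500)
        y = 50 + 20 * np.sin(2 * np.pi * x / 120) + rng.normal(0, 3, 500)
        ours = smooth_profile(MedianProfile("r", y), 0.1).values
        ref = reference_lowess(y, 0.1)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_matches_reference_at_default_span(self):
        rng = np.random.default_rng(1)
        y = rng.poisson(60, 300).astype(float)
        ours = smooth_profile(MedianProfile("r", y), 0.03).values
        ref = reference_lowess(y, 0.03)
        assert np.allclose(ours, ref, atol=1e-8)

    def test_statsmodels_agrees_loosely(self):
        # statsmodels defines its window slightly differently; smoothed
        # curves should still track each other closely at a matched frac
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        x = np.arange(400, dtype=float)
        y = 50 + 20 * np.sin(2 * np.pi * x / 100) + rng.normal(0, 2, 400)
        ours = smooth_profile(MedianProfile("r", y), 0.1).values
        theirs = sm.nonparametric.lowess(y, x, frac=0.1, it=0, return_sorted=False)
        assert np.abs(ours - theirs).mean() < 1.0

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile(MedianProfile("r", np.array([1.0])))


def S(values):
    return SmoothedProfile("r", np.asarray(values, dtype=float), 0.03)


class TestDetectExtrema:
    @pytest.mark.parametrize(
        "curve, peaks, troughs",
        [
            ([1, 2, 3, 2, 1], [2], [0, 4]),
            ([5, 5, 5, 5, 5], [], []),
            ([1, 2, 2, 2, 1], [2], [0, 4]),
            ([3, 1, 2, 1, 3], [2], [1, 3]),
            ([1, 3, 1, 3, 1], [1, 3], [0, 2, 4]),
        ],
    )
    def test_examples(self, curve, peaks, troughs):
        p, t = detect_extrema(S(curve))
        assert p == peaks
        assert t == troughs

    def test_endpoints_never_peaks(self):
        p, t = detect_extrema(S([5, 3, 1, 2, 1]))
        assert 0 not in p and 4 not in p

    @given(st.lists(st.integers(0, 2), min_size=3, max_size=12))
    @settings(max_examples=300, derandomize=True)
    def test_matches_brute_force_scan(self, curve):
        p, t = detect_extrema(S(curve))
        bp, bt = brute_force_extrema(curve)
        assert p == bp
        assert t == bt

    def test_exhaustive_short_curves(self):
        for n in range(3, 8):
            for curve in itertools.product((0, 1, 2), repeat=n):
                assert detect_extrema(S(curve)) == brute_force_extrema(curve), curve

    def test_alternation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            curve = rng.integers(0, 5, 30)
            p, t = detect_extrema(S(curve))
            for a, b in zip(p, p[1:]):
                assert sum(1 for x in t if a < x < b) == 1


class TestPeakGeometry:
    def test_toy_curve_geometry(self):
        sm = S([1, 2, 3, 2, 1])
        p, t = detect_extrema(sm)
        (peak,) = peak_geometry(sm, p, t)
        assert peak.height == 3
        assert peak.base == 1
        assert peak.width == 4

    def test_symmetric_two_peak_curve(self):
        sm = S([1, 2, 4, 2, 1, 2, 4, 2, 1])
        p, t = detect_extrema(sm)
        peaks = peak_geometry(sm, p, t)
        assert len(peaks) == 2
        assert peaks[0].height == peaks[1].height == 4
        assert peaks[0].base == peaks[1].base
        assert peaks[0].width == peaks[1].width

    def test_zero_troughs_hit_the_floor(self):
        sm = S([0, 2, 5, 2, 0])
        p, t = detect_extrema(sm)
        (peak,) = peak_geometry(sm, p, t, b_floor=0.5)
        assert peak.base == 0.5
        assert peak.height == 5


class TestUeScore:
    def test_uniform_region_scores_one(self):
        assert ue_score([], 300).ue == 1.0

    def test_direct_formula(self):
        peak = Peak(0, height=100, base=50, width=150, left_trough_pos=0, right_trough_pos=150)
        assert ue_score([peak], 300).ue == pytest.approx(4.0)

    def test_additivity_over_peaks(self):
        peak = Peak(0, 100, 50, 150, 0, 150)
        assert ue_score([peak, peak], 300).ue == pytest.approx(8.0)

    def test_floor_at_one(self):
        weak = Peak(0, 10, 10, 299, 0, 299)  # contributes ~1.003
        tiny = Peak(0, 10, 10, 300, 0, 300)  # contributes exactly 1
        assert ue_score([tiny], 300).ue == 1.0
        assert ue_score([weak], 300).ue >= 1.0


def bump_matrix(amplitude, length=300, n=5, base=50, width=25, center=None):
    center = length // 2 if center is None else center
    x = np.arange(length)
    mu = base * (1 + amplitude * np.exp(-0.5 * ((x - center) / width) ** 2))
    depths = np.tile(np.round(mu).astype(int), (n, 1))
    cat = make_catalog([("G", "chr1", 1000, 1000 + length)])
    return make_matrix(cat, {"G|0": depths}), cat


class TestUeForMatrix:
    def test_uniform_cohort_scores_one(self, uniform_matrix):
        (res,) = ue_for_matrix(uniform_matrix(depth=50))
        assert res.ue == 1.0
        assert res.n_peaks == 0

    def test_planted_bump_exceeds_one(self):
        m, _ = bump_matrix(2.0)
        (res,) = ue_for_matrix(m)
        assert res.ue > 1.0
        assert res.n_peaks >= 1

    def test_library_size_invariance(self):
        m, cat = bump_matrix(2.0)
        (res,) = ue_for_matrix(m)
        doubled = make_matrix(cat, {"G|0": 2 * m.region_depths("G|0")})
        (res2,) = ue_for_matrix(doubled)
        assert res2.ue == pytest.approx(res.ue, abs=1e-9)

    def test_zero_trough_increases_ue(self):
        m, cat = bump_matrix(0.0)  # flat
        (flat,) = ue_for_matrix(m)
        depths = m.region_depths("G|0").copy()
        depths[:, 120:180] = 0  # coverage collapse inside the region
        holed = make_matrix(cat, {"G|0": depths})
        (res,) = ue_for_matrix(holed)
        assert flat.ue == 1.0
        assert res.ue > flat.ue

    def test_short_regions_skipped(self):
        cat = make_catalog([("G", "chr1", 0, 3), ("H", "chr1", 10, 310)])
        m = make_matrix(
            cat, {"G|0": np.full((3, 3), 50), "H|0": np.full((3, 300), 50)}
        )
        results = ue_for_matrix(m)
        assert [r.region_id for r in results] == ["H|0"]

    def test_ue_at_least_one_on_random_cohorts(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            cat = make_catalog([("G", "chr1", 0, 120)])
            m = make_matrix(cat, {"G|0": rng.integers(0, 200, (4, 120))})
            (res,) = ue_for_matrix(m)
            assert res.ue >= 1.0

    def test_second_peak_increases_ue(self):
        m1, _ = bump_matrix(2.0, length=400, center=100)
        x = np.arange(400)
        mu = 50 * (1 + 2.0 * np.exp(-0.5 * ((x - 100) / 25) ** 2)
                   + 2.0 * np.exp(-0.5 * ((x - 300) / 25) ** 2))
        cat = make_catalog([("G", "chr1", 0, 400)])
        m2 = make_matrix(cat, {"G|0": np.tile(np.round(mu).astype(int), (5, 1))})
        (one,) = ue_for_matrix(m1)
        (two,) = ue_for_matrix(m2)
        assert two.ue > one.ue
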