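"""Unevenness (U_E) scoring of cohort coverage profiles.

The score measures local non-uniformity of coverage over a target
region. Pipeline, per region:

1. per-base median depth across the cohort;
2. LOWESS smoothing with a proportional span (default 0.03 — the window
   at each base holds ``max(ceil(span * L_R), 4)`` nearest positions,
   tricube weights, a degree-1 local fit and no robustness iterations);
3. hill-climbing extremum detection: a scan over all base positions for
   points with no increasing or decreasing neighbours, with plateaus
   collapsed to their centre; region endpoints may delimit peak bases as
   troughs but are never themselves peaks;
4. peak geometry: height H = smoothed coverage at the apex, base
   B = mean of the two flanking trough values (floored at 0.5 reads so a
   zero-coverage trough yields a finite ratio), width W = distance in bp
   between the flanking troughs;
5. U_E = sum over peaks of (H/B) / (W/L_R); an empty peak set (uniform
   coverage) scores exactly 1, and the score is floored at 1.

Because H and B are absolute coverage levels, scaling the whole profile
by a constant leaves every H/B ratio — and hence U_E — unchanged: the
score is library-size invariant as long as coverage scales
proportionally. A region where coverage collapses to zero breaks that
proportionality (H grows, B does not) and the score rises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .annotation import RegionCatalog
from .coverage_io import DepthMatrix

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.03
DEFAULT_B_FLOOR = 0.5
MIN_UE_REGION_LENGTH = 4


@dataclass
class MedianProfile:
    region_id: str
    values: np.ndarray  # per-base cohort median depth


@dataclass
class SmoothedProfile:
    region_id: str
    values: np.ndarray
    span: float


@dataclass
class Peak:
    """One coverage peak with its geometry on the smoothed curve."""

    apex_pos: int
    height: float  # H: smoothed coverage at the apex
    base: float  # B: baseline under the peak (floored)
    width: int  # W: bp between flanking troughs
    left_trough_pos: int
    right_trough_pos: int


@dataclass
class UeResult:
    region_id: str
    ue: float
    peaks: list[Peak] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def median_profile(region_depths: np.ndarray, region_id: str = "") -> MedianProfile:
    """Position-wise median depth across samples (midpoint for even N)."""
    region_depths = np.atleast_2d(np.asarray(region_depths))
    return MedianProfile(region_id, np.median(region_depths, axis=0))


def _window_bounds(n: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-position [lo, hi) bounds of the k nearest indices on a unit grid.

    Ties in distance are broken toward the lower index, so the window at
    position i is [i - ceil((k-1)/2), ...] clipped into range.
    """
    half_left = (k - 1 + 1) // 2  # ties toward lower index
    lo = np.arange(n) - half_left
    lo = np.clip(lo, 0, max(n - k, 0))
    return lo, lo + k


def smooth_profile(
    profile: MedianProfile, span: float = DEFAULT_SPAN
) -> SmoothedProfile:
    """LOWESS smoothing of the median profile with a proportional span.

    The span is the fraction of the region's base positions contributing
    to each locally fitted value, so short exons keep fine structure
    while long exons have small bumps smoothed over.
    """
    y = np.asarray(profile.values, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("smoothing needs a region of length >= 2")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    k = min(max(math.ceil(span * n), 4), n)
    x = np.arange(n, dtype=float)
    lo, hi = _window_bounds(n, k)
    fitted = np.empty(n)
    for i in range(n):
        xs = x[lo[i] : hi[i]]
        ys = y[lo[i] : hi[i]]
        if ys.max() == ys.min():  # constant window: fit is exact, skip arithmetic
            fitted[i] = ys[0]
            continue
        d = np.abs(xs - i)
        dmax = d.max()
        if dmax == 0:
            fitted[i] = y[i]
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        sw = w.sum()
        xbar = (w * xs).sum() / sw
        ybar = (w * ys).sum() / sw
        sxx = (w * (xs - xbar) ** 2).sum()
        if sxx <= 1e-12:
            fitted[i] = ybar
        else:
            slope = (w * (xs - xbar) * (ys - ybar)).sum() / sxx
            fitted[i] = ybar + slope * (i - xbar)
    return SmoothedProfile(profile.region_id, fitted, span)


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of equal values as [start, end] inclusive index pairs."""
    runs: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(values)):
        if values[i] != values[start]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(values) - 1))
    return runs


def detect_extrema(smoothed: SmoothedProfile) -> tuple[list[int], list[int]]:
    """Hill-climbing scan for interior extrema of the smoothed curve.

    Returns (peaks, troughs) as base-index lists. A plateau (run of
    equal values) collapses to its centre position, floor((start+end)/2),
    and classifies by the values flanking the run; a run touching a
    region boundary classifies by its single interior flank. The
    boundary positions themselves are trough-eligible but never peaks
    (a monotone edge is not capture unevenness), so a peak whose
    collapsed centre lands exactly on position 0 or L_R - 1 is
    suppressed — an edge plateau wide enough to centre in the interior
    still counts, which is what makes a coverage hole in an otherwise
    flat region detectable. Between consecutive peaks exactly one
    trough is kept (the lowest; leftmost on ties), so peaks and troughs
    alternate.
    """
    v = np.asarray(smoothed.values, dtype=float)
    n = v.size
    if n < 3:
        return [], []
    runs = _runs(v)
    peaks: list[int] = []
    troughs: list[int] = []
    for start, end in runs:
        center = (start + end) // 2
        left = v[start - 1] if start > 0 else None
        right = v[end + 1] if end < n - 1 else None
        here = v[start]
        if left is None and right is None:
            continue  # flat curve: no extrema
        higher = ((left is None or left > here)
                  and (right is None or right > here))
        lower = ((left is None or left < here)
                 and (right is None or right < here))
        if lower and center not in (0, n - 1):
            peaks.append(center)
        elif higher:
            troughs.append(center)

    # enforce alternation: one (lowest) trough between consecutive peaks
    if len(peaks) > 1:
        kept: list[int] = []
        tr = np.asarray(troughs)
        for a, b in zip(peaks, peaks[1:]):
            between = tr[(tr > a) & (tr < b)]
            if between.size:
                best = between[np.argmin(v[between])]
                kept.append(int(best))
        outside = [t for t in troughs if t < peaks[0] or t > peaks[-1]]
        troughs = sorted(outside + kept)
    return peaks, troughs


def peak_geometry(
    smoothed: SmoothedProfile,
    peaks: list[int],
    troughs: list[int],
    b_floor: float = DEFAULT_B_FLOOR,
) -> list[Peak]:
    """Height / base / width of each peak from its flanking troughs.

    A peak's flanks are the nearest trough on each side, falling back to
    the region endpoint when no trough exists on that side. B is the
    mean of the two flanking trough values, floored at ``b_floor`` reads
    so that a complete coverage dropout still yields a finite H/B.
    """
    v = np.asarray(smoothed.values, dtype=float)
    n = v.size
    out: list[Peak] = []
    tr = sorted(troughs)
    for apex in peaks:
        left_candidates = [t for t in tr if t < apex]
        right_candidates = [t for t in tr if t > apex]
        lt = left_candidates[-1] if left_candidates else 0
        rt = right_candidates[0] if right_candidates else n - 1
        base = max((v[lt] + v[rt]) / 2.0, b_floor)
        out.append(
            Peak(
                apex_pos=int(apex),
                height=float(v[apex]),
                base=float(base),
                width=int(rt - lt),
                left_trough_pos=int(lt),
                right_trough_pos=int(rt),
            )
        )
    return out


def ue_score(peaks: list[Peak], region_length: int, region_id: str = "") -> UeResult:
    """U_E = sum over peaks of (H/B) / (W/L_R), floored at 1.

    An empty peak set means uniformly distributed coverage and scores
    exactly 1.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if not peaks:
        return UeResult(region_id, 1.0, [])
    total = 0.0
    for p in peaks:
        if p.base <= 0:
            raise RuntimeError("peak base must be positive after flooring")
        total += (p.height / p.base) / (p.width / region_length)
    return UeResult(region_id, max(total, 1.0), list(peaks))


def ue_for_region(
    region_depths: np.ndarray,
    region_id: str = "",
    span: float = DEFAULT_SPAN,
    b_floor: float = DEFAULT_B_FLOOR,
) -> UeResult:
    """Full unevenness pipeline for one region's (n_samples, L_R) depths."""
    med = median_profile(region_depths, region_id)
    smoothed = smooth_profile(med, span)
    peaks, troughs = detect_extrema(smoothed)
    geoms = peak_geometry(smoothed, peaks, troughs, b_floor)
    return ue_score(geoms, med.values.size, region_id)


def ue_for_matrix(
    matrix: DepthMatrix,
    catalog: RegionCatalog | None = None,
    span: float = DEFAULT_SPAN,
    b_floor: float = DEFAULT_B_FLOOR,
    min_region_length: int = MIN_UE_REGION_LENGTH,
) -> list[UeResult]:
    """Unevenness for every catalog region long enough to smooth.

    Regions shorter than ``min_region_length`` bp are skipped with a
    logged notice (a meaningful local fit needs a few bases).
    """
    catalog = catalog or matrix.catalog
    out: list[UeResult] = []
    for r in catalog:
        if r.length < min_region_length:
            logger.info("region %s (%d bp) too short for U_E; skipped", r.region_id, r.length)
            continue
        out.append(
            ue_for_region(matrix.region_depths(r.region_id), r.region_id, span, b_floor)
        )
    return out


def smoothed_median_profiles(
    matrix: DepthMatrix,
    catalog: RegionCatalog | None = None,
    span: float = DEFAULT_SPAN,
    min_region_length: int = MIN_UE_REGION_LENGTH,
) -> dict[str, SmoothedProfile]:
    """Smoothed cohort-median profile per region (for trough analyses)."""
    catalog = catalog or matrix.catalog
    out: dict[str, SmoothedProfile] = {}
    for r in catalog:
        if r.length < min_region_length:
            continue
        out[r.region_id] = smooth_profile(
            median_profile(matrix.region_depths(r.region_id), r.region_id), span
        )
    return out
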