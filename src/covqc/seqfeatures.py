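"""Sequence-context annotation: GC content and repeat/trough concordance.

High GC exons capture poorly; repeat elements under a target often drag
coverage down to an "extremely low" trough (smoothed cohort median
below 10 reads). This module quantifies both associations: per-region
GC fractions grouped by coverage class, and the fraction of regions
whose extremely low troughs coincide with a repeat interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .annotation import GenomicInterval, RegionCatalog
from .ccs import CcsResult
from .unevenness import SmoothedProfile, detect_extrema

EXTREME_TROUGH_DEPTH = 10.0
GC_BAND_LOW = 0.3
GC_BAND_HIGH = 0.7


@dataclass
class GcAnnotation:
    region_id: str
    gc_fraction: float
    n_ambiguous: int


def _gc_counts(seq: str) -> tuple[int, int, int]:
    """(gc, unambiguous, ambiguous) base counts, case-insensitive."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    return gc, gc + at, len(s) - gc - at


def gc_content(
    catalog: RegionCatalog, reference: str | Path | Mapping[str, str]
) -> list[GcAnnotation]:
    """Per-region GC fraction (G+C over unambiguous bases) from a FASTA.

    ``reference`` may also be a plain chrom -> sequence mapping, which
    is convenient for simulated genomes.
    """
    if isinstance(reference, (str, Path)):
        fasta = Fasta(str(reference))
        get = lambda chrom, s, e: str(fasta[chrom][s:e])
        names = set(fasta.keys())
    else:
        get = lambda chrom, s, e: reference[chrom][s:e]
        names = set(reference.keys())
    out: list[GcAnnotation] = []
    for r in catalog:
        iv = r.interval
        if iv.chrom not in names:
            raise KeyError(f"chromosome {iv.chrom} missing from reference")
        gc, unamb, amb = _gc_counts(get(iv.chrom, iv.start, iv.end))
        frac = gc / unamb if unamb else float("nan")
        out.append(GcAnnotation(r.region_id, frac, amb))
    return out


def gene_gc_content(
    catalog: RegionCatalog, reference: str | Path | Mapping[str, str]
) -> list[GcAnnotation]:
    """Gene-level GC pooled over all exonic bases of each gene."""
    per_region = {g.region_id: g for g in gc_content(catalog, reference)}
    out: list[GcAnnotation] = []
    for gene, regions in catalog.genes().items():
        # pool counts, not fractions: reconstruct from lengths
        gc_total = unamb_total = amb_total = 0
        for r in regions:
            ann = per_region[r.region_id]
            unamb = r.length - ann.n_ambiguous
            gc_total += round(ann.gc_fraction * unamb) if unamb else 0
            unamb_total += unamb
            amb_total += ann.n_ambiguous
        frac = gc_total / unamb_total if unamb_total else float("nan")
        out.append(GcAnnotation(gene, frac, amb_total))
    return out


def gc_band(gc: float) -> str:
    """GC band label: <30%, 30-70% (inclusive) or >70%."""
    if gc < GC_BAND_LOW:
        return "<30%"
    if gc <= GC_BAND_HIGH:
        return "30-70%"
    return ">70%"


def gc_class_densities(
    gc_annotations: Sequence[GcAnnotation],
    ccs_results: Sequence[CcsResult],
    cut: float = 0.2,
) -> pd.DataFrame:
    """GC values grouped by coverage class, plot-ready.

    Returns one row per region with columns region_id, gc, ccs,
    coverage_class in {adequate, low} at the given CCS cut, and gc_band.
    The 'all' group is the whole frame.
    """
    ccs_by_id = {r.region_id: r.ccs for r in ccs_results}
    rows = []
    for g in gc_annotations:
        if g.region_id not in ccs_by_id:
            continue
        c = ccs_by_id[g.region_id]
        rows.append(
            {
                "region_id": g.region_id,
                "gc": g.gc_fraction,
                "ccs": c,
                "coverage_class": "low" if c > cut else "adequate",
                "gc_band": gc_band(g.gc_fraction),
            }
        )
    if not rows:
        raise ValueError("no shared region ids between GC and CCS inputs")
    return pd.DataFrame(rows)


def gc_band_counts(densities: pd.DataFrame) -> pd.DataFrame:
    """Region counts per (coverage_class, gc_band) including 'all'."""
    bands = ["<30%", "30-70%", ">70%"]
    out = []
    for cls in ["all", "adequate", "low"]:
        sub = densities if cls == "all" else densities[densities["coverage_class"] == cls]
        counts = sub["gc_band"].value_counts()
        out.append({"coverage_class": cls, **{b: int(counts.get(b, 0)) for b in bands}})
    return pd.DataFrame(out)


@dataclass
class TroughCall:
    """An extremely low trough: a maximal run of smoothed median < 10X."""

    region_id: str
    start: int  # bp within region, inclusive
    end: int  # bp within region, exclusive
    median_depth_at_trough: float


def low_trough_intervals(
    smoothed: SmoothedProfile, depth_cut: float = EXTREME_TROUGH_DEPTH
) -> list[TroughCall]:
    """Extents of extremely low troughs on one smoothed profile.

    Each detected trough position whose smoothed value is below the cut
    is expanded to the maximal contiguous run of sub-cut values
    containing it; runs shared by several troughs are reported once.
    """
    v = np.asarray(smoothed.values)
    _, troughs = detect_extrema(smoothed)
    below = v < depth_cut
    calls: list[TroughCall] = []
    seen: set[tuple[int, int]] = set()
    for t in troughs:
        if not below[t]:
            continue
        s = t
        while s > 0 and below[s - 1]:
            s -= 1
        e = t
        while e < v.size - 1 and below[e + 1]:
            e += 1
        key = (s, e + 1)
        if key not in seen:
            seen.add(key)
            calls.append(
                TroughCall(smoothed.region_id, s, e + 1, float(v[s : e + 1].min()))
            )
    return calls


@dataclass
class ConcordanceResult:
    per_region: pd.DataFrame  # region_id, L_R, n_low_troughs, repeat_overlap
    fraction_overall: float
    fraction_gt_200bp: float


def trough_repeat_concordance(
    smoothed_profiles: Mapping[str, SmoothedProfile],
    repeats: Sequence[GenomicInterval],
    catalog: RegionCatalog,
    depth_cut: float = EXTREME_TROUGH_DEPTH,
) -> ConcordanceResult:
    """Do extremely low troughs coincide with repeat elements?

    For every region with at least one extremely low trough, flag
    whether any repeat interval overlaps any trough extent by >= 1 bp
    (in genomic coordinates). The summary fraction's denominator is the
    set of regions having such troughs, reported overall and for
    regions longer than 200 bp.
    """
    rep_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in repeats:
        rep_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    rows = []
    for r in catalog:
        prof = smoothed_profiles.get(r.region_id)
        if prof is None:
            continue
        calls = low_trough_intervals(prof, depth_cut)
        if not calls:
            continue
        flagged = False
        for call in calls:
            gs = r.interval.start + call.start
            ge = r.interval.start + call.end
            for rs, re_ in rep_by_chrom.get(r.interval.chrom, []):
                if gs < re_ and rs < ge:
                    flagged = True
                    break
            if flagged:
                break
        rows.append(
            {
                "region_id": r.region_id,
                "L_R": r.length,
                "n_low_troughs": len(calls),
                "repeat_overlap": flagged,
            }
        )
    per_region = pd.DataFrame(rows, columns=["region_id", "L_R", "n_low_troughs", "repeat_overlap"])
    if len(per_region):
        overall = float(per_region["repeat_overlap"].mean())
        big = per_region[per_region["L_R"] > 200]
        gt200 = float(big["repeat_overlap"].mean()) if len(big) else float("nan")
    else:
        overall = gt200 = float("nan")
    return ConcordanceResult(per_region, overall, gt200)
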