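"""Cohort-level statistics and plot-ready tables.

Covers the standard downstream summaries of the two coverage metrics:
the low-coverage gene count table, the Pearson correlation between
region length and unevenness, the Friedman rank test of matched region
scores across capture platforms, and a Manhattan-style layout of gene
scores along cumulative chromosome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RegionCatalog, chrom_sort_key
from .ccs import CcsResult, classify
from .unevenness import UeResult

P_DISPLAY_FLOOR = 2.2e-16


def format_pvalue(p: float) -> str:
    """Scientific-notation p-value, displayed as a floor below 2.2e-16."""
    if p < P_DISPLAY_FLOOR:
        return "< 2.2e-16"
    return f"{p:.3g}"


@dataclass
class SummaryTable:
    """Low-coverage gene counts at the CCS > 0.2 and CCS > 0.5 cuts.

    The columns nest: every gene above 0.5 is also above 0.2.
    """

    n_genes: int
    n_ccs_gt_02: int
    pct_ccs_gt_02: float
    n_ccs_gt_05: int
    pct_ccs_gt_05: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genes": self.n_genes,
                    "genes_ccs_gt_0.2": self.n_ccs_gt_02,
                    "pct_ccs_gt_0.2": self.pct_ccs_gt_02,
                    "genes_ccs_gt_0.5": self.n_ccs_gt_05,
                    "pct_ccs_gt_0.5": self.pct_ccs_gt_05,
                }
            ]
        )


def summary_table(gene_results: Sequence[CcsResult]) -> SummaryTable:
    """Count genes above the low-coverage CCS cuts (strict >)."""
    if not gene_results:
        raise ValueError("no gene results")
    n = len(gene_results)
    gt02 = sum(1 for r in gene_results if r.ccs > 0.2)
    gt05 = sum(1 for r in gene_results if r.ccs > 0.5)
    return SummaryTable(
        n, gt02, round(100.0 * gt02 / n, 1), gt05, round(100.0 * gt05 / n, 1)
    )


def pearson_length_ue(
    ue_results: Sequence[UeResult], catalog: RegionCatalog
) -> tuple[float, float]:
    """Pearson r (and p) between region length L_R and unevenness U_E.

    Returns (nan, nan) when either variable has zero variance.
    """
    lengths, ues = [], []
    for res in ue_results:
        if np.isfinite(res.ue):
            lengths.append(catalog.get(res.region_id).length)
            ues.append(res.ue)
    if len(lengths) < 3:
        raise ValueError("need >=3 regions with finite unevenness")
    x, y = np.asarray(lengths, float), np.asarray(ues, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class FriedmanResult:
    statistic: float
    df: int
    pvalue: float
    n_regions: int
    n_groups: int


def friedman_test(matched_scores: np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Friedman rank test on an R x K matrix of matched region scores.

    Rows are regions (blocks), columns are platforms (treatments). Ties
    within a row take average ranks and the statistic carries the usual
    tie correction; the p-value uses the chi-square approximation with
    df = K - 1. Missing cells are rejected — the design must be matched.
    """
    a = np.asarray(matched_scores, dtype=float)
    if a.ndim != 2:
        raise ValueError("matched_scores must be 2-D (regions x platforms)")
    n, k = a.shape
    if k < 2 or n < 2:
        raise ValueError("need >=2 platforms and >=2 matched regions")
    if not np.all(np.isfinite(a)):
        raise ValueError("matched design is incomplete (non-finite cells)")
    ranks = np.apply_along_axis(stats.rankdata, 1, a)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: per row, sum of (t^3 - t) over tied groups
    ties = 0.0
    for row in a:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:  # every row fully tied
        stat = 0.0
    else:
        stat = stat / c
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return FriedmanResult(float(stat), df, p, n, k)


def friedman_long_regions(
    ue_by_platform: Mapping[str, Sequence[UeResult]],
    catalog: RegionCatalog,
    min_length: int = 400,
) -> FriedmanResult:
    """Friedman test of U_E across platforms, restricted to long regions.

    Platforms are matched on region_id; only regions longer than
    ``min_length`` bp present in every platform enter the test.
    """
    frames = {
        plat: {r.region_id: r.ue for r in results}
        for plat, results in ue_by_platform.items()
    }
    platforms = list(frames)
    common = set.intersection(*(set(f) for f in frames.values()))
    keep = sorted(
        rid for rid in common if catalog.get(rid).length > min_length
    )
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 matched regions > {min_length} bp")
    mat = np.array([[frames[p][rid] for p in platforms] for rid in keep])
    return friedman_test(mat)


def manhattan_table(
    gene_results: Sequence[CcsResult], catalog: RegionCatalog
) -> pd.DataFrame:
    """Per-gene CCS laid out along cumulative chromosome coordinates.

    x = prefix-sum offset of the chromosome + gene start; rows are
    ordered by (chromosome, start) so the frame plots directly as a
    Manhattan-style figure.
    """
    genes = catalog.genes()
    chrom_extent: dict[str, int] = {}
    for r in catalog:
        c = r.interval.chrom
        chrom_extent[c] = max(chrom_extent.get(c, 0), r.interval.end)
    offsets: dict[str, int] = {}
    cum = 0
    for c in sorted(chrom_extent, key=chrom_sort_key):
        offsets[c] = cum
        cum += chrom_extent[c]
    rows = []
    for res in gene_results:
        regions = genes.get(res.region_id)
        if regions is None:
            continue
        chrom = regions[0].interval.chrom
        start = min(r.interval.start for r in regions)
        rows.append(
            {
                "gene": res.region_id,
                "chrom": chrom,
                "start": start,
                "x": offsets[chrom] + start,
                "ccs": res.ccs,
                "class": classify(res.ccs),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        by=["chrom", "start"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
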