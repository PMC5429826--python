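"""Cohort Coverage Sparseness (CCS) scoring and low-coverage classification.

A base is deficient when its read depth is strictly below the cutoff
(default 10 reads). Each sample's deficient fraction over a region is
#(c_i < cutoff) / L_R; the CCS score is the median of that fraction
across the cohort, so it ranges from 0 (fully covered in at least half
the samples) to 1 (deficient everywhere in at least half the samples).

Gene-level CCS pools all exonic bases of the gene into one region of
interest (denominator = total exonic length) before taking the cohort
median. Genes are classified adequate / low / severe at the CCS > 0.2
and CCS > 0.5 cuts (strict inequalities; the boundary values are not
low coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import RegionCatalog
from .coverage_io import DepthMatrix

DEFICIENCY_CUTOFF = 10
CCS_LOW_CUT = 0.2
CCS_SEVERE_CUT = 0.5


@dataclass
class CcsResult:
    """CCS of one region (exon or gene) with its per-sample fractions."""

    region_id: str
    per_sample_deficient_fraction: np.ndarray
    ccs: float
    n_samples: int


def deficient_fraction(depths: np.ndarray, threshold: int = DEFICIENCY_CUTOFF) -> float:
    """Fraction of bases with depth strictly below the cutoff."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty depth profile")
    return float(np.count_nonzero(depths < threshold) / depths.size)


def ccs_score(
    region_depths: np.ndarray,
    region_id: str = "",
    threshold: int = DEFICIENCY_CUTOFF,
) -> CcsResult:
    """CCS of one region from its (n_samples, L_R) depth array."""
    region_depths = np.atleast_2d(np.asarray(region_depths))
    n, length = region_depths.shape
    if n < 1 or length < 1:
        raise ValueError("need >=1 sample and >=1 base")
    fractions = np.count_nonzero(region_depths < threshold, axis=1) / length
    return CcsResult(region_id, fractions, float(np.median(fractions)), n)


def exon_ccs(
    matrix: DepthMatrix, threshold: int = DEFICIENCY_CUTOFF
) -> list[CcsResult]:
    """CCS for every catalog region (exon) in the matrix."""
    return [
        ccs_score(matrix.region_depths(r.region_id), r.region_id, threshold)
        for r in matrix.catalog
    ]


def gene_ccs(
    matrix: DepthMatrix,
    catalog: RegionCatalog | None = None,
    threshold: int = DEFICIENCY_CUTOFF,
    aggregate: str = "pool",
) -> list[CcsResult]:
    """Gene-level CCS.

    ``aggregate='pool'`` (default) concatenates all of a gene's exonic
    bases into one region of interest before computing per-sample
    fractions; ``aggregate='median'`` instead takes the per-gene median
    of exon CCS values.
    """
    catalog = catalog or matrix.catalog
    if aggregate not in ("pool", "median"):
        raise ValueError("aggregate must be 'pool' or 'median'")
    results: list[CcsResult] = []
    for gene, regions in catalog.genes().items():
        if aggregate == "pool":
            deficient = np.zeros(matrix.n_samples, dtype=np.int64)
            total = 0
            for r in regions:
                d = matrix.region_depths(r.region_id)
                deficient += np.count_nonzero(d < threshold, axis=1)
                total += r.length
            fractions = deficient / total
            results.append(
                CcsResult(gene, fractions, float(np.median(fractions)), matrix.n_samples)
            )
        else:
            per_exon = [
                ccs_score(matrix.region_depths(r.region_id), r.region_id, threshold).ccs
                for r in regions
            ]
            results.append(
                CcsResult(
                    gene,
                    np.asarray(per_exon),
                    float(np.median(per_exon)),
                    matrix.n_samples,
                )
            )
    return results


def classify(ccs: float) -> str:
    """Map a CCS value to {adequate, low, severe} at the 0.2 / 0.5 cuts."""
    if not (0.0 <= ccs <= 1.0):
        raise ValueError(f"ccs {ccs} outside [0, 1]")
    if ccs > CCS_SEVERE_CUT:
        return "severe"
    if ccs > CCS_LOW_CUT:
        return "low"
    return "adequate"


@dataclass
class ChromosomeSummary:
    """2 x K contingency of low-coverage vs adequate genes by chromosome."""

    table: pd.DataFrame  # index: chromosome; columns: adequate, low_coverage
    statistic: float
    df: int
    pvalue: float
    small_expected_counts: bool


def chromosome_summary(
    gene_results: list[CcsResult], catalog: RegionCatalog
) -> ChromosomeSummary:
    """Chi-square test of low-coverage gene proportion across chromosomes.

    Low coverage pools the low and severe classes (CCS > 0.2). Pearson
    chi-square without continuity correction, df = K - 1.
    """
    gene_chrom = {
        gene: regions[0].interval.chrom for gene, regions in catalog.genes().items()
    }
    rows: dict[str, list[int]] = {}
    for res in gene_results:
        chrom = gene_chrom.get(res.region_id)
        if chrom is None:
            continue
        counts = rows.setdefault(chrom, [0, 0])
        if classify(res.ccs) == "adequate":
            counts[0] += 1
        else:
            counts[1] += 1
    if len(rows) < 2:
        raise ValueError("need genes on >=2 chromosomes")
    from .annotation import chrom_sort_key

    table = pd.DataFrame.from_dict(rows, orient="index", columns=["adequate", "low_coverage"])
    table = table.loc[sorted(table.index, key=chrom_sort_key)]
    observed = table.to_numpy().T  # 2 x K
    stat, p, df, expected = stats.chi2_contingency(observed, correction=False)
    return ChromosomeSummary(table, float(stat), int(df), float(p), bool((expected < 1).any()))


def ccs_table(
    results: list[CcsResult], catalog: RegionCatalog, by_gene: bool = False
) -> pd.DataFrame:
    """Tidy per-exon or per-gene CCS table with coordinates and class labels."""
    rows = []
    genes = catalog.genes()
    for res in results:
        if by_gene:
            regions = genes[res.region_id]
            chrom = regions[0].interval.chrom
            start = min(r.interval.start for r in regions)
            end = max(r.interval.end for r in regions)
            length = sum(r.length for r in regions)
            gene = res.region_id
        else:
            r = catalog.get(res.region_id)
            chrom, start, end = r.interval.chrom, r.interval.start, r.interval.end
            length, gene = r.length, r.gene_symbol
        rows.append(
            {
                "region_id": res.region_id,
                "gene": gene,
                "chrom": chrom,
                "start": start,
                "end": end,
                "L_R": length,
                "ccs": res.ccs,
                "class": classify(res.ccs),
                "n_samples": res.n_samples,
            }
        )
    return pd.DataFrame(rows)
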