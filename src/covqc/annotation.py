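"""Consensus exome annotation and the region catalog.

Exome capture metrics are computed over a catalog of target exon regions:
per gene, exons from all transcripts are merged into maximal disjoint
intervals, then intersected with the capture-kit target BED and restricted
to autosomes 1-22. All interval I/O uses BED convention (0-based,
half-open); conversion to the 1-based coordinates of per-base depth files
happens only at the depth-file boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript of a gene: an ordered set of exon intervals."""

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {e.chrom} "
                    f"but transcript on {self.chrom}"
                )


@dataclass(frozen=True)
class Region:
    """A catalog entry: one merged exon of one gene."""

    region_id: str
    gene_symbol: str
    exon_index: int
    interval: GenomicInterval

    @property
    def length(self) -> int:
        """Region length L_R in bp."""
        return len(self.interval)


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX."""
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    if m:
        return (int(m.group(1)), "")
    return (10**9, chrom)


@dataclass
class RegionCatalog:
    """Sorted collection of target exon regions, unique ids, no same-gene overlap."""

    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regions = sorted(
            self.regions,
            key=lambda r: (chrom_sort_key(r.interval.chrom), r.interval.start),
        )
        seen: set[str] = set()
        for r in self.regions:
            if r.region_id in seen:
                raise ValueError(f"duplicate region_id {r.region_id}")
            seen.add(r.region_id)
        by_gene: dict[str, list[Region]] = {}
        for r in self.regions:
            by_gene.setdefault(r.gene_symbol, []).append(r)
        for gene, regs in by_gene.items():
            regs = sorted(regs, key=lambda r: (r.interval.chrom, r.interval.start))
            for a, b in zip(regs, regs[1:]):
                if a.interval.overlaps(b.interval):
                    raise ValueError(f"overlapping regions within gene {gene}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def get(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def genes(self) -> dict[str, list[Region]]:
        out: dict[str, list[Region]] = {}
        for r in self.regions:
            out.setdefault(r.gene_symbol, []).append(r)
        return out

    def total_bases(self) -> int:
        return sum(r.length for r in self.regions)


def _union_intervals(intervals: Sequence[GenomicInterval]) -> list[tuple[int, int]]:
    """Sweep-line union of intervals (same chromosome) -> maximal disjoint spans."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_transcript_exons(transcripts: Iterable[TranscriptRecord]) -> RegionCatalog:
    """Merge overlapping exons of each gene across transcripts.

    Per gene, the union of all transcript exons is expressed as maximal
    disjoint intervals; exon indices are assigned in ascending genomic
    order. A gene whose transcripts sit on more than one chromosome is
    rejected with a logged diagnostic (it cannot form a single catalog
    entry set).
    """
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_symbol, []).append(t)

    regions: list[Region] = []
    for gene in sorted(by_gene):
        ts = by_gene[gene]
        chroms = {t.chrom for t in ts}
        if len(chroms) > 1:
            logger.warning(
                "gene %s maps to multiple chromosomes %s; skipped",
                gene,
                sorted(chroms),
            )
            continue
        chrom = chroms.pop()
        strand = ts[0].strand
        exons = [e for t in ts for e in t.exons]
        for i, (s, e) in enumerate(_union_intervals(exons)):
            regions.append(
                Region(
                    region_id=f"{gene}|{i}",
                    gene_symbol=gene,
                    exon_index=i,
                    interval=GenomicInterval(chrom, s, e, strand),
                )
            )
    return RegionCatalog(regions)


def intersect_targets(
    catalog: RegionCatalog,
    targets: Sequence[GenomicInterval],
    autosomes_only: bool = True,
) -> RegionCatalog:
    """Restrict the catalog to bases covered by the capture targets.

    Regions are split where targets fragment them; exon indices are
    re-assigned per gene in ascending genomic order. By default only
    autosomes 1-22 are retained.
    """
    targets_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in targets:
        targets_by_chrom.setdefault(iv.chrom, []).append(iv)
    merged_targets = {
        chrom: _union_intervals(ivs) for chrom, ivs in targets_by_chrom.items()
    }

    pieces: dict[str, list[tuple[str, str, int, int]]] = {}
    for r in catalog:
        chrom = r.interval.chrom
        if autosomes_only and chrom not in _AUTOSOMES:
            continue
        for ts, te in merged_targets.get(chrom, []):
            s = max(r.interval.start, ts)
            e = min(r.interval.end, te)
            if s < e:
                pieces.setdefault(r.gene_symbol, []).append(
                    (chrom, r.interval.strand, s, e)
                )

    regions: list[Region] = []
    for gene in sorted(pieces):
        ordered = sorted(pieces[gene], key=lambda p: (chrom_sort_key(p[0]), p[2]))
        for i, (chrom, strand, s, e) in enumerate(ordered):
            regions.append(
                Region(f"{gene}|{i}", gene, i, GenomicInterval(chrom, s, e, strand))
            )
    if not regions:
        logger.warning("catalog/target intersection is empty")
    return RegionCatalog(regions)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (>=3 columns, 0-based half-open) into intervals."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval [{start},{end})"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_catalog(catalog: RegionCatalog, path: str | Path) -> None:
    """Write the catalog as 6-column BED (name = gene|exon_index)."""
    with open(path, "w") as fh:
        for r in catalog:
            iv = r.interval
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.region_id}\t0\t{strand}\n"
            )


def read_catalog_bed(path: str | Path) -> RegionCatalog:
    """Read a catalog previously written by :func:`write_catalog`.

    Plain 3-column BED is also accepted; region ids are then synthesized
    as chrom:start-end with gene = region_id.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            if len(fields) >= 4 and "|" in fields[3]:
                name = fields[3]
                gene, idx = name.rsplit("|", 1)
                exon_index = int(idx)
            else:
                name = f"{chrom}:{start}-{end}"
                gene, exon_index = name, 0
            regions.append(
                Region(name, gene, exon_index, GenomicInterval(chrom, start, end, strand))
            )
    return RegionCatalog(regions)


def read_transcript_table(path: str | Path) -> list[TranscriptRecord]:
    """Read a refFlat-style TSV of transcripts.

    Columns: gene, transcript, chrom, strand, comma-separated exon starts,
    comma-separated exon ends (0-based half-open, trailing commas allowed).
    """
    out: list[TranscriptRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            gene, tx, chrom, strand = fields[:4]
            starts = [int(x) for x in fields[4].rstrip(",").split(",")]
            ends = [int(x) for x in fields[5].rstrip(",").split(",")]
            if len(starts) != len(ends):
                raise ValueError(f"{path}:{lineno}: starts/ends length mismatch")
            exons = tuple(
                GenomicInterval(chrom, s, e, strand if strand in "+-" else ".")
                for s, e in sorted(zip(starts, ends))
            )
            out.append(TranscriptRecord(gene, tx, chrom, strand, exons))
    return out
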