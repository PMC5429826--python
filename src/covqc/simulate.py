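"""Synthetic cohort depth simulator.

Generates per-base depth cohorts over a region catalog with
controllable uniformity so every metric in the package can be exercised
without external sequencing data. The generative model per base is

    depth = noise( base_mean_depth * bump * dropout * gc multipliers )

with noise in {none, poisson, negative binomial}. Bumps are Gaussian
coverage excesses (capture-probe pile-ups), dropouts are multiplicative
depth collapses over a sub-interval (repeat- or GC-driven capture
failure), and the optional GC response maps a region's GC fraction to a
depth multiplier. Defaults emulate a well-behaved capture cohort:
mean depth 100X (comfortably above the 75X QC cut) with Poisson
counting noise.

Everything is deterministic under the config seed: each sample draws
from its own ``default_rng((seed, sample_index))`` substream, so files
are byte-identical across runs and machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .annotation import GenomicInterval, Region, RegionCatalog
from .coverage_io import DepthMatrix

NoiseModel = Literal["none", "poisson", "nb"]


@dataclass
class Bump:
    """Gaussian coverage excess centred within a region."""

    region_id: str
    center: int  # bp within region
    width: int  # Gaussian sigma in bp
    amplitude: float  # multiplier at the centre, >= 0 adds (1 + a*exp(...))


@dataclass
class Dropout:
    """Multiplicative depth collapse over [start, end) within a region."""

    region_id: str
    start: int
    end: int
    multiplier: float  # in [0, 1]; 0 = complete dropout


@dataclass
class SimConfig:
    n_samples: int = 5
    base_mean_depth: float = 100.0
    noise: NoiseModel = "poisson"
    nb_dispersion: float = 10.0  # variance = mu + mu^2 / k
    bumps: list[Bump] = field(default_factory=list)
    dropouts: list[Dropout] = field(default_factory=list)
    gc_response: Callable[[float], float] | None = None
    gc_by_region: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_mean_depth <= 0:
            raise ValueError("base_mean_depth must be positive")
        if self.n_samples < 1:
            raise ValueError("need >= 1 sample")
        for d in self.dropouts:
            if not (0.0 <= d.multiplier <= 1.0):
                raise ValueError("dropout multiplier must be in [0, 1]")


def default_catalog(
    n_genes: int = 5,
    exons_per_gene: int = 2,
    mean_exon_length: int = 200,
    seed: int = 0,
    chrom_cycle: Sequence[str] = ("chr1", "chr2"),
) -> RegionCatalog:
    """A small synthetic exon catalog with lognormal exon lengths.

    Lengths are drawn with median ``mean_exon_length`` bp (typical exon
    scale); exons of a gene are laid head to tail with 500 bp gaps, and
    genes cycle over the given chromosomes.
    """
    rng = np.random.default_rng(seed)
    regions: list[Region] = []
    cursors = {c: 1000 for c in chrom_cycle}
    for g in range(n_genes):
        gene = f"GENE{g:03d}"
        chrom = chrom_cycle[g % len(chrom_cycle)]
        pos = cursors[chrom]
        for e in range(exons_per_gene):
            length = max(int(rng.lognormal(math.log(mean_exon_length), 0.5)), 50)
            regions.append(
                Region(
                    f"{gene}|{e}", gene, e,
                    GenomicInterval(chrom, pos, pos + length, "+"),
                )
            )
            pos += length + 500
        cursors[chrom] = pos + 2000
    return RegionCatalog(regions)


def expected_profile(config: SimConfig, region: Region) -> np.ndarray:
    """Noise-free expected depth per base of one region."""
    x = np.arange(region.length, dtype=float)
    mu = np.full(region.length, config.base_mean_depth, dtype=float)
    for b in config.bumps:
        if b.region_id == region.region_id:
            mu *= 1.0 + b.amplitude * np.exp(-0.5 * ((x - b.center) / b.width) ** 2)
    for d in config.dropouts:
        if d.region_id == region.region_id:
            s, e = max(d.start, 0), min(d.end, region.length)
            mu[s:e] *= d.multiplier
    if config.gc_response is not None and config.gc_by_region is not None:
        gc = config.gc_by_region.get(region.region_id)
        if gc is not None:
            mu *= config.gc_response(gc)
    return mu


def simulate_cohort(config: SimConfig, catalog: RegionCatalog) -> DepthMatrix:
    """Draw a full cohort depth matrix under the config's model."""
    matrix = DepthMatrix(catalog, [f"S{i:03d}" for i in range(config.n_samples)])
    for si in range(config.n_samples):
        rng = np.random.default_rng((config.seed, si))
        for region in catalog:
            mu = expected_profile(config, region)
            if config.noise == "none":
                depths = np.round(mu).astype(np.int64)
            elif config.noise == "poisson":
                depths = rng.poisson(mu).astype(np.int64)
            elif config.noise == "nb":
                k = config.nb_dispersion
                # NB as Poisson-gamma mixture: mean mu, variance mu + mu^2/k
                lam = np.where(mu > 0, rng.gamma(k, np.maximum(mu, 1e-12) / k), 0.0)
                depths = rng.poisson(lam).astype(np.int64)
            else:
                raise ValueError(f"unknown noise model {config.noise!r}")
            matrix.region_depths(region.region_id)[si] = depths
    return matrix


def write_depth_files(
    matrix: DepthMatrix,
    outdir: str | Path,
    dialect: str = "coverage",
) -> list[Path]:
    """Write one depth TSV per sample in a BEDTools output dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for si, sample in enumerate(matrix.samples):
        path = outdir / f"{sample}.{dialect}.tsv"
        with open(path, "w") as fh:
            for region in matrix.catalog:
                depths = matrix.region_depths(region.region_id)[si]
                iv = region.interval
                if dialect == "coverage":
                    for off0, d in enumerate(depths):
                        fh.write(
                            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{region.region_id}"
                            f"\t0\t{iv.strand}\t{off0 + 1}\t{int(d)}\n"
                        )
                elif dialect == "genomecov":
                    for off0, d in enumerate(depths):
                        fh.write(f"{iv.chrom}\t{iv.start + off0 + 1}\t{int(d)}\n")
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
        paths.append(path)
    return paths


def _write_fasta(sequences: Mapping[str, str], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def synthetic_reference(
    catalog: RegionCatalog, gc_by_region: Mapping[str, float], seed: int = 0
) -> dict[str, str]:
    """A synthetic chrom -> sequence mapping realising target GC fractions.

    Background sequence is 50% GC; each catalog region's bases are drawn
    to match its requested GC fraction.
    """
    rng = np.random.default_rng(seed)
    extents: dict[str, int] = {}
    for r in catalog:
        extents[r.interval.chrom] = max(
            extents.get(r.interval.chrom, 0), r.interval.end + 100
        )
    genomes = {
        chrom: rng.choice(list("ACGT"), size=n) for chrom, n in extents.items()
    }
    for r in catalog:
        gc = gc_by_region.get(r.region_id, 0.5)
        bases = rng.choice(
            list("GCAT"), size=r.length, p=[gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
        )
        genomes[r.interval.chrom][r.interval.start : r.interval.end] = bases
    return {c: "".join(g) for c, g in genomes.items()}


def make_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical named fixtures used by the tests and examples.

    uniform          5 samples, constant 50X over one 300 bp region
    single-bump      one Gaussian pile-up in the region centre
    two-bump         two well-separated pile-ups
    edge-dropout     358 bp region, full depth to base 200, collapse after
    gc-graded        five exons at GC 0.2/0.35/0.5/0.65/0.8 + FASTA
    repeat-trough    planted dropout under a repeat BED interval
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def one_region_catalog(name: str, length: int, chrom: str = "chr1") -> RegionCatalog:
        return RegionCatalog(
            [Region(f"{name}|0", name, 0, GenomicInterval(chrom, 1000, 1000 + length, "+"))]
        )

    from .annotation import write_catalog

    # uniform: ccs 0, ue 1 end to end
    cat = one_region_catalog("UNIFORM", 300)
    cfg = SimConfig(n_samples=5, base_mean_depth=50, noise="none", seed=seed)
    mat = simulate_cohort(cfg, cat)
    d = outdir / "uniform"
    write_depth_files(mat, d)
    write_catalog(cat, d / "catalog.bed")
    written["uniform"] = d

    # single-bump
    cat = one_region_catalog("BUMP1", 300)
    cfg = SimConfig(
        n_samples=5, base_mean_depth=50, noise="none",
        bumps=[Bump("BUMP1|0", 150, 25, 2.0)], seed=seed,
    )
    mat = simulate_cohort(cfg, cat)
    d = outdir / "single-bump"
    write_depth_files(mat, d)
    write_catalog(cat, d / "catalog.bed")
    written["single-bump"] = d

    # two-bump
    cat = one_region_catalog("BUMP2", 400)
    cfg = SimConfig(
        n_samples=5, base_mean_depth=50, noise="none",
        bumps=[Bump("BUMP2|0", 100, 20, 2.0), Bump("BUMP2|0", 300, 20, 2.0)],
        seed=seed,
    )
    mat = simulate_cohort(cfg, cat)
    d = outdir / "two-bump"
    write_depth_files(mat, d)
    write_catalog(cat, d / "catalog.bed")
    written["two-bump"] = d

    # edge-dropout: high depth bases 1-200, collapse over 200-358
    cat = one_region_catalog("EDGE", 358)
    cfg = SimConfig(
        n_samples=5, base_mean_depth=100, noise="none",
        dropouts=[Dropout("EDGE|0", 200, 358, 0.0)], seed=seed,
    )
    mat = simulate_cohort(cfg, cat)
    d = outdir / "edge-dropout"
    write_depth_files(mat, d)
    write_catalog(cat, d / "catalog.bed")
    written["edge-dropout"] = d

    # gc-graded exon set with a synthetic reference
    regions = [
        Region(f"GC{i}|0", f"GC{i}", 0, GenomicInterval("chr1", 1000 + i * 500, 1200 + i * 500, "+"))
        for i in range(5)
    ]
    cat = RegionCatalog(regions)
    gc = {f"GC{i}|0": v for i, v in enumerate([0.2, 0.35, 0.5, 0.65, 0.8])}
    genome = synthetic_reference(cat, gc, seed=seed)
    d = outdir / "gc-graded"
    d.mkdir(parents=True, exist_ok=True)
    _write_fasta(genome, d / "reference.fa")
    write_catalog(cat, d / "catalog.bed")
    response = lambda g: max(1.0 - 2.0 * max(g - 0.6, 0.0), 0.05)
    cfg = SimConfig(
        n_samples=5, base_mean_depth=50, noise="none",
        gc_response=response, gc_by_region=gc, seed=seed,
    )
    mat = simulate_cohort(cfg, cat)
    write_depth_files(mat, d)
    written["gc-graded"] = d

    # repeat-trough: dropout exactly under a repeat interval
    cat = one_region_catalog("REP", 300)
    cfg = SimConfig(
        n_samples=5, base_mean_depth=60, noise="none",
        dropouts=[Dropout("REP|0", 120, 180, 0.0)], seed=seed,
    )
    mat = simulate_cohort(cfg, cat)
    d = outdir / "repeat-trough"
    write_depth_files(mat, d)
    write_catalog(cat, d / "catalog.bed")
    with open(d / "repeats.bed", "w") as fh:
        fh.write("chr1\t1130\t1170\trepeat1\n")  # genomic coords of the dropout
    written["repeat-trough"] = d
    return written
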