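import numpy as np
import pytest

from covqc.annotation import GenomicInterval, Region, RegionCatalog
from covqc.coverage_io import DepthMatrix


def make_catalog(entries):
    """entries: list of (gene, chrom, start, end); one region per tuple."""
    counters = {}
    regions = []
    for gene, chrom, start, end in entries:
        i = counters.get(gene, 0)
        counters[gene] = i + 1
        regions.append(Region(f"{gene}|{i}", gene, i, GenomicInterval(chrom, start, end, "+")))
    return RegionCatalog(regions)


def make_matrix(catalog, depths_by_region, samples=None):
    """depths_by_region: region_id -> (n_samples, L) array-like."""
    first = next(iter(depths_by_region.values()))
    n = np.atleast_2d(np.asarray(first)).shape[0]
    samples = samples or [f"S{i}" for i in range(n)]
    m = DepthMatrix(catalog, samples)
    for rid, arr in depths_by_region.items():
        m.region_depths(rid)[:] = np.atleast_2d(np.asarray(arr))
    return m


@pytest.fixture
def one_region_catalog():
    def build(length, gene="G", chrom="chr1", start=1000):
        return make_catalog([(gene, chrom, start, start + length)])
    return build


@pytest.fixture
def uniform_matrix(one_region_catalog):
    def build(depth=50, n_samples=5, length=300):
        cat = one_region_catalog(length)
        rid = cat.region_ids[0]
        return make_matrix(cat, {rid: np.full((n_samples, length), depth, dtype=int)})
    return build
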