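"""Per-base depth file parsing, cohort depth matrix assembly, and sample QC.

Two BEDTools output dialects are supported:

* ``coverage -d``: the catalog BED columns followed by a 1-based offset
  within the region and an integer depth (>=5 tab-separated columns; the
  last two are offset and depth, the first three chrom/start/end).
* ``genomecov -d``: chrom, 1-based genomic position, depth (3 columns).

Positions absent from a file are depth 0 — an uncovered base is a real
observation of zero coverage, not missing data, because the sparseness
score counts every base below the deficiency cutoff.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Literal, Sequence

import numpy as np

from .annotation import RegionCatalog

logger = logging.getLogger(__name__)

Dialect = Literal["auto", "coverage", "genomecov"]


@dataclass
class DepthProfile:
    """Per-base integer read depths of one sample over one catalog region."""

    region_id: str
    sample_id: str
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be a 1-D vector")
        if not np.issubdtype(self.depths.dtype, np.integer):
            if not np.all(self.depths == np.floor(self.depths)):
                raise ValueError("depths must be integers")
            self.depths = self.depths.astype(np.int64)
        if np.any(self.depths < 0):
            raise ValueError("depths must be >= 0")


@dataclass
class SampleQc:
    """Mean per-base depth over all catalog bases and the QC verdict."""

    sample_id: str
    mean_target_depth: float
    passed: bool


class DepthMatrix:
    """Complete region x sample x base depth store for a cohort.

    Every (region, sample) cell is present; bases with no depth record
    are zero-filled at parse time.
    """

    def __init__(self, catalog: RegionCatalog, samples: Sequence[str]):
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample_id")
        self.catalog = catalog
        self.samples = list(samples)
        self._data: dict[str, np.ndarray] = {
            r.region_id: np.zeros((len(self.samples), r.length), dtype=np.int64)
            for r in catalog
        }

    def set_profile(self, profile: DepthProfile) -> None:
        region = self.catalog.get(profile.region_id)
        if len(profile.depths) != region.length:
            raise ValueError(
                f"profile length {len(profile.depths)} != region length "
                f"{region.length} for {profile.region_id}"
            )
        si = self.samples.index(profile.sample_id)
        self._data[profile.region_id][si] = profile.depths

    def region_depths(self, region_id: str) -> np.ndarray:
        """(n_samples, L_R) integer depth array for one region."""
        return self._data[region_id]

    def profile(self, region_id: str, sample_id: str) -> DepthProfile:
        si = self.samples.index(sample_id)
        return DepthProfile(region_id, sample_id, self._data[region_id][si].copy())

    def sample_mean_depth(self, sample_id: str) -> float:
        si = self.samples.index(sample_id)
        total = sum(int(self._data[rid][si].sum()) for rid in self._data)
        nbases = self.catalog.total_bases()
        return total / nbases if nbases else 0.0

    def subset_samples(self, keep: Sequence[str]) -> "DepthMatrix":
        out = DepthMatrix(self.catalog, list(keep))
        idx = [self.samples.index(s) for s in keep]
        for rid, arr in self._data.items():
            out._data[rid] = arr[idx].copy()
        return out

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _open_text(path: str | Path) -> IO[str]:
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, "rt")
    return open(p)


def _detect_dialect(first_fields: list[str]) -> str:
    if len(first_fields) == 3:
        return "genomecov"
    if len(first_fields) >= 5:
        return "coverage"
    raise ValueError(
        f"cannot detect depth-file dialect from {len(first_fields)} columns"
    )


def _parse_depth(token: str, path: str | Path, lineno: int) -> int:
    try:
        d = int(token)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer depth {token!r}") from exc
    if d < 0:
        raise ValueError(f"{path}:{lineno}: negative depth {d}")
    return d


def read_depth_file(
    path: str | Path,
    catalog: RegionCatalog,
    sample_id: str | None = None,
    dialect: Dialect = "auto",
) -> list[DepthProfile]:
    """Parse one sample's per-base depth file against the catalog.

    Returns one :class:`DepthProfile` per catalog region; positions not
    listed in the file get depth 0 and positions outside the catalog are
    ignored. Duplicate records for the same base are an error.
    """
    if sample_id is None:
        name = Path(path).name
        for suf in (".gz", ".tsv", ".txt", ".depth", ".cov"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        sample_id = name

    arrays = {r.region_id: np.zeros(r.length, dtype=np.int64) for r in catalog}
    seen = {r.region_id: np.zeros(r.length, dtype=bool) for r in catalog}

    # genomecov lookup: chrom -> [(start, end, region_id)]
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    by_coords: dict[tuple[str, int, int], str] = {}
    for r in catalog:
        iv = r.interval
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, r.region_id))
        by_coords[(iv.chrom, iv.start, iv.end)] = r.region_id
    for spans in by_chrom.values():
        spans.sort()

    mode: str | None = None if dialect == "auto" else dialect
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if mode is None:
                mode = _detect_dialect(fields)
            if mode == "genomecov":
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                chrom, pos1, depth = fields[0], fields[1], fields[2]
                try:
                    pos0 = int(pos1) - 1  # 1-based -> 0-based
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad position") from exc
                d = _parse_depth(depth, path, lineno)
                for s, e, rid in by_chrom.get(chrom, []):
                    if s <= pos0 < e:
                        off = pos0 - s
                        if seen[rid][off]:
                            raise ValueError(
                                f"{path}:{lineno}: duplicate position for {rid}"
                            )
                        arrays[rid][off] = d
                        seen[rid][off] = True
            else:
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: expected >=5 columns")
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                    off1 = int(fields[-2])  # 1-based offset within region
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
                d = _parse_depth(fields[-1], path, lineno)
                rid = by_coords.get((chrom, start, end))
                if rid is None:
                    continue  # region not in catalog
                if not (1 <= off1 <= end - start):
                    raise ValueError(
                        f"{path}:{lineno}: offset {off1} outside region"
                    )
                if seen[rid][off1 - 1]:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate position for {rid}"
                    )
                arrays[rid][off1 - 1] = d
                seen[rid][off1 - 1] = True

    return [
        DepthProfile(r.region_id, sample_id, arrays[r.region_id]) for r in catalog
    ]


def assemble_matrix(
    profile_lists: Iterable[list[DepthProfile]], catalog: RegionCatalog
) -> DepthMatrix:
    """Assemble per-sample profile lists into a complete cohort matrix.

    Sample order is input order; a sample appearing twice is an error.
    """
    lists = list(profile_lists)
    samples: list[str] = []
    for plist in lists:
        sids = {p.sample_id for p in plist}
        if len(sids) != 1:
            raise ValueError("each profile list must belong to one sample")
        sid = sids.pop()
        if sid in samples:
            raise ValueError(f"duplicate sample_id {sid}")
        samples.append(sid)
    matrix = DepthMatrix(catalog, samples)
    for plist in lists:
        for p in plist:
            matrix.set_profile(p)
    return matrix


def qc_filter(
    matrix: DepthMatrix, min_mean_depth: float = 75.0
) -> tuple[DepthMatrix, list[SampleQc]]:
    """Drop samples whose mean catalog-base depth is below the threshold.

    The cutoff is inclusive: a sample at exactly the threshold passes.
    The returned QC table covers all input samples.
    """
    qc: list[SampleQc] = []
    keep: list[str] = []
    for sid in matrix.samples:
        mean = matrix.sample_mean_depth(sid)
        ok = mean >= min_mean_depth
        qc.append(SampleQc(sid, mean, ok))
        if ok:
            keep.append(sid)
        else:
            logger.info("sample %s fails QC: mean depth %.2f < %g", sid, mean, min_mean_depth)
    if not keep:
        raise ValueError(
            "all samples fail the mean-depth QC filter; lower min_mean_depth "
            "to retain this cohort"
        )
    return matrix.subset_samples(keep), qc
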