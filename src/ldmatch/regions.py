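"""Gene annotations, genic/non-genic partition of markers, and reference sets.

Overlapping or book-ended gene annotations are merged into disjoint genic
regions (overlapping genes tend to be co-inherited, so they are treated as a
single unit of analysis).  Every SNP is then assigned to exactly one region:
the merged genic interval containing it, or the maximal run of consecutive
non-genic SNPs it lies in.  Genic regions with enough SNPs become the
reference sets of the matched-pairs comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MarkerMap


@dataclass(frozen=True)
class Interval:
    """A 1-based, inclusive genomic interval."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on "
                f"{self.chromosome}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Region:
    """A labeled set of consecutive SNP columns on one chromosome."""

    chromosome: str
    snp_indices: np.ndarray
    label: str  # G | IG | IG_prime | non_genic_segment | candidate
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.int64)
        if self.snp_indices.size == 0:
            raise ValueError("region must contain at least one SNP")
        if np.any(np.diff(self.snp_indices) <= 0):
            raise ValueError("region SNP indices must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return int(self.snp_indices.size)


def read_bed(path) -> list[Interval]:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    return [
        Interval(str(r.chrom), int(r.start) + 1, int(r.end))
        for r in df.itertuples(index=False)
    ]


def read_gff3(path, feature_type: str = "gene") -> list[Interval]:
    """Read gene intervals from GFF3 (already 1-based inclusive)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5 or parts[2] != feature_type:
                continue
            out.append(Interval(parts[0], int(parts[3]), int(parts[4])))
    return out


def merge_overlapping_genes(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping, nested and book-ended intervals per chromosome.

    Returns the minimal disjoint set covering the input union, sorted by
    (chromosome, start).  Adjacent intervals (next start == current end + 1)
    are merged too, matching the usual bedtools-merge behaviour.
    """
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    merged: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(Interval(chrom, cur_start, cur_end))
    return merged


def partition_markers(
    mmap: MarkerMap, merged_genic: list[Interval]
) -> tuple[MarkerMap, list[Region], list[Region]]:
    """Assign every SNP to a genic region or a non-genic segment.

    A SNP with ``start <= pos <= end`` of a merged genic interval is genic
    (boundaries inclusive); all other SNPs are non-genic and grouped into
    maximal runs of consecutive non-genic SNPs per chromosome.  Fills
    ``region_class`` and ``region_index`` on the map and returns it together
    with the genic regions and non-genic segments (both in genomic order).
    """
    M = len(mmap)
    region_class = np.empty(M, dtype=object)
    region_index = np.full(M, -1, dtype=np.int64)

    genic_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    iv_list = sorted(merged_genic, key=lambda x: (x.chromosome, x.start))
    for gid, iv in enumerate(iv_list):
        genic_by_chrom.setdefault(iv.chromosome, ([], [], []))  # type: ignore
    tmp: dict[str, list] = {}
    for gid, iv in enumerate(iv_list):
        tmp.setdefault(iv.chromosome, []).append((iv.start, iv.end, gid))
    for chrom, rows in tmp.items():
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        gids = np.array([r[2] for r in rows], dtype=np.int64)
        genic_by_chrom[chrom] = (starts, ends, gids)

    genic_members: dict[int, list[int]] = {}
    for chrom in mmap.chromosomes:
        sl = mmap.chromosome_slice(chrom)
        pos = mmap.pos[sl]
        offset = sl.start
        if chrom in genic_by_chrom:
            starts, ends, gids = genic_by_chrom[chrom]
            k = np.searchsorted(starts, pos, side="right") - 1
            inside = (k >= 0) & (pos <= ends[np.clip(k, 0, len(ends) - 1)])
            for local_i in np.flatnonzero(inside):
                gid = int(gids[k[local_i]])
                i = offset + int(local_i)
                region_class[i] = "genic"
                region_index[i] = gid
                genic_members.setdefault(gid, []).append(i)
            nong = ~inside
        else:
            nong = np.ones(len(pos), dtype=bool)
        for local_i in np.flatnonzero(nong):
            region_class[offset + int(local_i)] = "non_genic"

    genic_regions = [
        Region(
            chromosome=str(mmap.chrom[members[0]]),
            snp_indices=np.asarray(members, dtype=np.int64),
            label="G",
            span=(int(mmap.pos[members[0]]), int(mmap.pos[members[-1]])),
        )
        for gid, members in sorted(genic_members.items())
    ]

    # maximal runs of consecutive non-genic SNPs, never crossing chromosomes
    nongenic_segments: list[Region] = []
    seg_id_offset = len(iv_list)
    run: list[int] = []
    for i in range(M):
        is_nong = region_class[i] == "non_genic"
        breaks = run and (not is_nong or mmap.chrom[i] != mmap.chrom[run[-1]])
        if breaks:
            nongenic_segments.append(_segment(mmap, run))
            run = []
        if is_nong:
            run.append(i)
    if run:
        nongenic_segments.append(_segment(mmap, run))
    for s, seg in enumerate(nongenic_segments):
        region_index[seg.snp_indices] = seg_id_offset + s

    mmap.region_class = region_class
    mmap.region_index = region_index
    return mmap, genic_regions, nongenic_segments


def _segment(mmap: MarkerMap, run: list[int]) -> Region:
    return Region(
        chromosome=str(mmap.chrom[run[0]]),
        snp_indices=np.asarray(run, dtype=np.int64),
        label="non_genic_segment",
        span=(int(mmap.pos[run[0]]), int(mmap.pos[run[-1]])),
    )


def eligible_reference_sets(
    genic_regions: list[Region], min_snps: int = 10
) -> list[Region]:
    """Genic regions with at least ``min_snps`` SNPs (smaller reference sets
    give unstable matches and are excluded), in genomic order."""
    return [r for r in genic_regions if r.n_snps >= min_snps]


def regions_to_dataframe(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chromosome for r in regions],
            "start": [r.span[0] if r.span else -1 for r in regions],
            "end": [r.span[1] if r.span else -1 for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "label": [r.label for r in regions],
        }
    )
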