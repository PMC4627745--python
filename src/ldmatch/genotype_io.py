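"""Phased haplotype ingestion, genotype quality control and marker metadata.

The comparison framework operates on a complete, phased haplotype matrix:
rows are haplotypes (two per phased diploid sample, one per fully inbred /
haploid sample) and columns are biallelic SNPs.  Phasing and imputation are
upstream concerns; anything unphased or missing at ingestion time is a hard
error.  Genotype-level quality control (sample missingness, SNP missingness,
minor allele frequency) is applied to raw 0/1/2 genotype matrices *before*
conversion to haplotypes, mirroring the usual array-data workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam


class GenotypeIOError(ValueError):
    """Raised for malformed or unsupported genotype input."""


class QCError(ValueError):
    """Raised when quality control cannot produce a usable matrix."""


@dataclass
class GenotypeQCConfig:
    """Thresholds for genotype-matrix quality control.

    Parameters
    ----------
    max_snp_missing:
        SNPs with a missing-call fraction greater than or equal to this are
        removed (default 0.01).
    min_maf:
        SNPs with minor allele frequency below this are removed (default 0.01).
    max_individual_missing:
        Samples with a missing-call fraction greater than or equal to this are
        removed first (default 0.05).
    """

    max_snp_missing: float = 0.01
    min_maf: float = 0.01
    max_individual_missing: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_snp_missing", "min_maf", "max_individual_missing"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class HaplotypePanel:
    """A complete phased haplotype matrix.

    ``alleles`` is an (n_haplotypes, n_snps) array of 0/1 allele indicators.
    Allele coding per column is arbitrary (ALT = 1 when read from VCF); all
    LD statistics downstream are invariant to relabeling a column.
    """

    alleles: np.ndarray
    sample_ids: list[str]
    ploidy_mode: str  # "diploid_phased" or "haploid"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 2:
            raise GenotypeIOError("allele matrix must be 2-dimensional")
        if self.alleles.shape[0] < 2:
            raise GenotypeIOError("panel needs at least 2 haplotype rows")
        if not np.isin(self.alleles, (0, 1)).all():
            raise GenotypeIOError("allele matrix entries must all be 0 or 1")
        self.alleles = self.alleles.astype(np.uint8, copy=False)
        if self.ploidy_mode not in ("diploid_phased", "haploid"):
            raise GenotypeIOError(f"unknown ploidy_mode {self.ploidy_mode!r}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]


@dataclass
class MarkerMap:
    """Per-SNP metadata aligned with the columns of a :class:`HaplotypePanel`.

    Positions are 1-based base pairs, strictly increasing within each
    chromosome; chromosomes occupy contiguous column blocks.  ``region_class``
    ("genic"/"non_genic") and ``region_index`` are filled by
    :func:`ldmatch.regions.partition_markers`.
    """

    chrom: np.ndarray
    pos: np.ndarray
    maf: np.ndarray
    region_class: np.ndarray | None = None
    region_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if not (len(self.chrom) == len(self.pos) == len(self.maf)):
            raise GenotypeIOError("marker map field lengths differ")
        if len(self.pos) and self.pos.min() < 1:
            raise GenotypeIOError("positions must be positive 1-based integers")
        if np.any(self.maf > 0.5 + 1e-12) or np.any(self.maf < 0):
            raise GenotypeIOError("MAF must lie in [0, 0.5]")
        # chromosomes must form contiguous blocks with increasing positions
        seen: set = set()
        prev_chrom = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise GenotypeIOError(
                        f"chromosome {c!r} appears in non-contiguous blocks"
                    )
                seen.add(c)
                prev_chrom = c
                prev_pos = -1
            if p <= prev_pos:
                raise GenotypeIOError(
                    f"positions not strictly increasing on chromosome {c!r} "
                    f"near position {p}"
                )
            prev_pos = p

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        out: list = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chromosome_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise KeyError(chrom)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos, "maf": self.maf})
        if self.region_class is not None:
            df["region_class"] = self.region_class
        if self.region_index is not None:
            df["region_index"] = self.region_index
        return df


def compute_maf(column: np.ndarray) -> float:
    """Minor allele frequency of a 0/1 allele column: min(f, 1 - f)."""
    col = np.asarray(column)
    if not np.isin(col, (0, 1)).all():
        raise GenotypeIOError("allele column must contain only 0/1")
    f = float(col.mean())
    return min(f, 1.0 - f)


def marker_map_from_panel(panel: HaplotypePanel, chrom, pos) -> MarkerMap:
    """Build a MarkerMap, recomputing MAF from the panel columns."""
    maf = np.minimum(panel.alleles.mean(axis=0), 1.0 - panel.alleles.mean(axis=0))
    return MarkerMap(chrom=np.asarray(chrom, dtype=object), pos=pos, maf=maf)


# ---------------------------------------------------------------------------
# VCF input / output
# ---------------------------------------------------------------------------

def read_phased_vcf(path) -> tuple[HaplotypePanel, MarkerMap]:
    """Read a phased biallelic-SNP VCF into a haplotype panel.

    Diploid samples must be phased (``|`` separator); haploid genotypes (one
    allele, e.g. from fully homozygous inbred lines exported as haploid) are
    accepted and yield one haplotype row per sample.  Multiallelic records,
    non-SNP alleles, unphased or missing genotypes are rejected.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise GenotypeIOError("VCF contains no samples")
        rows: list[list[int]] = []
        chroms: list[str] = []
        positions: list[int] = []
        ploidy: int | None = None
        for rec in vf:
            where = f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeIOError(f"record {where} is not biallelic")
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise GenotypeIOError(f"record {where} is not a SNP")
            rec_alleles: list[int] = []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    raise GenotypeIOError(
                        f"missing genotype at {where} for sample {s} "
                        "(imputation is out of scope)"
                    )
                if len(gt) == 2:
                    if not call.phased:
                        raise GenotypeIOError(
                            f"unphased genotype at {where} for sample {s}"
                        )
                    p = 2
                elif len(gt) == 1:
                    p = 1
                else:
                    raise GenotypeIOError(f"unsupported ploidy at {where}")
                if ploidy is None:
                    ploidy = p
                elif ploidy != p:
                    raise GenotypeIOError(f"mixed ploidy at {where}")
                rec_alleles.extend(int(a) for a in gt)
            if any(a not in (0, 1) for a in rec_alleles):
                raise GenotypeIOError(f"non-biallelic allele index at {where}")
            rows.append(rec_alleles)
            chroms.append(rec.chrom)
            positions.append(rec.pos)
    if not rows:
        raise GenotypeIOError("VCF contains no usable records")
    alleles = np.asarray(rows, dtype=np.uint8).T  # haplotypes x SNPs
    panel = HaplotypePanel(
        alleles=alleles,
        sample_ids=samples,
        ploidy_mode="diploid_phased" if ploidy == 2 else "haploid",
    )
    mmap = marker_map_from_panel(panel, np.asarray(chroms, dtype=object), positions)
    return panel, mmap


def write_phased_vcf(panel: HaplotypePanel, mmap: MarkerMap, path) -> None:
    """Write a panel as a minimal phased VCF (round-trips through
    :func:`read_phased_vcf`)."""
    if len(mmap) != panel.n_snps:
        raise GenotypeIOError("marker map length does not match panel")
    diploid = panel.ploidy_mode == "diploid_phased"
    if diploid and panel.n_haplotypes % 2:
        raise GenotypeIOError("diploid panel needs an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2 if diploid else panel.n_haplotypes
    sample_ids = panel.sample_ids
    if len(sample_ids) != n_samples:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in mmap.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in sample_ids)
            + "\n"
        )
        A = panel.alleles
        for j in range(panel.n_snps):
            if diploid:
                gts = [f"{A[2 * i, j]}|{A[2 * i + 1, j]}" for i in range(n_samples)]
            else:
                gts = [str(A[i, j]) for i in range(n_samples)]
            fh.write(
                f"{mmap.chrom[j]}\t{mmap.pos[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Plain haplotype-matrix input
# ---------------------------------------------------------------------------

def read_haplotype_matrix(hap_path, map_path) -> tuple[HaplotypePanel, MarkerMap]:
    """Read a whitespace-delimited 0/1 haplotype matrix (rows = haplotypes)
    plus a 3-column map file (chrom, pos, id)."""
    alleles = np.loadtxt(hap_path, dtype=np.uint8, ndmin=2)
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None, names=["chrom", "pos", "id"],
        dtype={"chrom": str},
    )
    if len(mp) != alleles.shape[1]:
        raise GenotypeIOError(
            f"map has {len(mp)} markers but matrix has {alleles.shape[1]} columns"
        )
    panel = HaplotypePanel(
        alleles=alleles,
        sample_ids=[f"H{i}" for i in range(alleles.shape[0])],
        ploidy_mode="haploid",
    )
    mmap = marker_map_from_panel(
        panel, mp["chrom"].to_numpy(dtype=object), mp["pos"].to_numpy()
    )
    return panel, mmap


# ---------------------------------------------------------------------------
# Genotype QC and inbred-line conversion
# ---------------------------------------------------------------------------

def apply_qc(
    genotypes: np.ndarray, config: GenotypeQCConfig | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quality-control a samples x SNPs genotype matrix coded 0/1/2 with
    missing entries as NaN (or any negative value).

    Filter order is fixed: (1) samples with missing fraction >=
    ``max_individual_missing``, then (2) SNPs with missing fraction >=
    ``max_snp_missing``, then (3) SNPs with MAF < ``min_maf``, MAF being
    computed on the non-missing calls of the retained samples.  Sample
    removal changes allele frequencies, hence the MAF filter runs last.

    Returns ``(filtered matrix, kept SNP indices, kept sample indices)``.
    """
    if config is None:
        config = GenotypeQCConfig()
    G = np.asarray(genotypes, dtype=float)
    if G.ndim != 2 or G.size == 0:
        raise QCError("genotype matrix is empty or not 2-dimensional")
    G = np.where(G < 0, np.nan, G)
    missing = np.isnan(G)
    if not np.isin(G[~missing], (0, 1, 2)).all():
        raise QCError("genotype entries must be 0, 1, 2 or missing")

    sample_missing = missing.mean(axis=1)
    keep_samples = np.flatnonzero(sample_missing < config.max_individual_missing)
    if keep_samples.size == 0:
        raise QCError("all samples removed by individual missingness filter")
    G = G[keep_samples]
    missing = np.isnan(G)

    snp_missing = missing.mean(axis=0)
    keep1 = snp_missing < config.max_snp_missing

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        alt_freq = np.nanmean(G, axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = keep1 & (maf >= config.min_maf)
    keep_snps = np.flatnonzero(keep)
    if keep_snps.size == 0:
        raise QCError("all SNPs removed by QC")
    return G[:, keep_snps], keep_snps, keep_samples


def haplotypes_from_inbred(
    genotypes: np.ndarray, sample_ids: list[str] | None = None
) -> HaplotypePanel:
    """Convert a complete, fully homozygous 0/2 genotype matrix (inbred
    lines) to a haploid panel: one haplotype row per sample."""
    G = np.asarray(genotypes, dtype=float)
    if np.isnan(G).any():
        raise GenotypeIOError("inbred genotype matrix still contains missing calls")
    if not np.isin(G, (0, 2)).all():
        raise GenotypeIOError(
            "inbred conversion requires fully homozygous genotypes (0/2 only)"
        )
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(G.shape[0])]
    return HaplotypePanel(
        alleles=(G // 2).astype(np.uint8),
        sample_ids=list(sample_ids),
        ploidy_mode="haploid",
    )
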