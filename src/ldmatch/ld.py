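"""Two-locus linkage disequilibrium statistics and region-level summaries.

For two biallelic loci with minor allele frequencies p1, p2 and observed
minor-minor gamete frequency p12, the gametic disequilibrium coefficient is

    D = p12 - p1 * p2,

and the squared correlation of the allele indicators is

    r^2 = D^2 / (p1 (1 - p1) p2 (1 - p2)).

Because the attainable range of r^2 depends on the allele frequencies, the
MAF-standardized measure r^2_s = r^2 / r^2_max divides by the maximum r^2
attainable at the given frequencies (D bounded by its feasible interval).
Region-level LD is summarized by the median (and mean) of all pairwise r^2
and r^2_s within a region, plus the multi-SNP haplotype diversity H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import HaplotypePanel, MarkerMap
from .regions import Region


class LdError(ValueError):
    """Raised for invalid LD computation inputs."""


@dataclass(frozen=True)
class TwoLocusFreqs:
    """Minor allele frequencies at two loci and the minor-minor gamete
    frequency, after orienting each locus to its minor allele."""

    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p1 <= 0.5 and 0.0 < self.p2 <= 0.5):
            raise LdError(f"MAFs must lie in (0, 0.5], got {self.p1}, {self.p2}")
        lo = max(0.0, self.p1 + self.p2 - 1.0)
        hi = min(self.p1, self.p2)
        if not (lo - 1e-12 <= self.p12 <= hi + 1e-12):
            raise LdError(
                f"p12={self.p12} infeasible for p1={self.p1}, p2={self.p2}"
            )


@dataclass(frozen=True)
class LdPair:
    """LD statistics for one unordered SNP pair (i < j)."""

    i: int
    j: int
    distance: int
    r2: float
    r2_max: float
    r2_s: float


@dataclass
class RegionLdSummary:
    """Medians and means of pairwise LD plus haplotype diversity for one
    region."""

    region: Region
    n_pairs: int
    median_r2: float
    median_r2s: float
    mean_r2: float
    mean_r2s: float
    H: float


def _orient_minor(col: np.ndarray) -> np.ndarray:
    """Flip a 0/1 column so that 1 denotes its minor allele."""
    col = np.asarray(col)
    return col if col.mean() <= 0.5 else 1 - col


def gamete_freqs(col_a: np.ndarray, col_b: np.ndarray) -> TwoLocusFreqs:
    """Observed two-locus gamete frequencies from two allele columns.

    Each column is oriented to its minor allele first; p12 is the fraction
    of haplotypes carrying the minor allele at both loci.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape or a.ndim != 1:
        raise LdError("columns must be 1-D and of equal length")
    if a.min() == a.max() or b.min() == b.max():
        raise LdError("monomorphic column passed to gamete_freqs")
    a = _orient_minor(a)
    b = _orient_minor(b)
    return TwoLocusFreqs(
        p1=float(a.mean()), p2=float(b.mean()), p12=float((a * b).mean())
    )


def disequilibrium_D(freqs: TwoLocusFreqs) -> float:
    """Gametic disequilibrium coefficient D = p12 - p1 p2."""
    return freqs.p12 - freqs.p1 * freqs.p2


def r_squared(freqs: TwoLocusFreqs) -> float:
    """Squared correlation r^2 = D^2 / (p1(1-p1) p2(1-p2))."""
    D = disequilibrium_D(freqs)
    denom = freqs.p1 * (1 - freqs.p1) * freqs.p2 * (1 - freqs.p2)
    return D * D / denom


def r2_max(p1: float, p2: float) -> float:
    """Maximum attainable r^2 given the two minor allele frequencies.

    D is bounded by its feasible interval
    [max(-p1 p2, -(1-p1)(1-p2)), min(p1(1-p2), (1-p1) p2)]; the maximizing D
    sits at whichever boundary has the larger magnitude.  For minor allele
    frequencies this reduces to
    min(p1,p2) (1 - max(p1,p2)) / ((1 - min(p1,p2)) max(p1,p2)).
    """
    if not (0.0 < p1 <= 0.5 and 0.0 < p2 <= 0.5):
        raise LdError(f"MAFs must lie in (0, 0.5], got {p1}, {p2}")
    # for minor allele frequencies the maximizing boundary is always
    # D_hi = pmin (1 - pmax) >= |D_lo| = p1 p2, and the ratio reduces to a
    # form that is exactly 1.0 when p1 == p2
    pmin, pmax = min(p1, p2), max(p1, p2)
    return (pmin * (1 - pmax)) / ((1 - pmin) * pmax)


def r2_standardized(r2: float, r2max: float, tol: float = 1e-9) -> float:
    """r^2_s = r^2 / r^2_max, clipped to [0, 1]."""
    if r2 > r2max + tol:
        raise LdError(f"r2={r2} exceeds r2_max={r2max} beyond tolerance")
    return float(np.clip(r2 / r2max, 0.0, 1.0))


def _pairwise_r2_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise r^2 over the columns of a minor-oriented 0/1
    matrix via the D-based formula.  Returns (p_minor, r2_matrix)."""
    N = X.shape[0]
    p = X.mean(axis=0)
    P12 = (X.T @ X) / N
    D = P12 - np.outer(p, p)
    var = p * (1 - p)
    denom = np.outer(var, var)
    return p, (D * D) / denom


def pairwise_ld(panel: HaplotypePanel, region: Region, mmap: MarkerMap) -> list[LdPair]:
    """All m(m-1)/2 within-region SNP pairs with distance, r^2, r^2_max and
    r^2_s."""
    idx = region.snp_indices
    if idx.size < 2:
        raise LdError("pairwise LD needs a region with at least 2 SNPs")
    X = panel.alleles[:, idx].astype(float)
    flip = X.mean(axis=0) > 0.5
    X[:, flip] = 1 - X[:, flip]
    p, R2 = _pairwise_r2_matrix(X)
    pos = mmap.pos[idx]
    iu, ju = np.triu_indices(idx.size, k=1)
    pmin = np.minimum(p[iu], p[ju])
    pmax = np.maximum(p[iu], p[ju])
    r2max = (pmin * (1 - pmax)) / ((1 - pmin) * pmax)
    r2 = R2[iu, ju]
    r2s = np.clip(r2 / r2max, 0.0, 1.0)
    dist = np.abs(pos[ju] - pos[iu])
    return [
        LdPair(
            i=int(idx[a]), j=int(idx[b]), distance=int(d),
            r2=float(v), r2_max=float(vm), r2_s=float(vs),
        )
        for a, b, d, v, vm, vs in zip(iu, ju, dist, r2, r2max, r2s)
    ]


def haplotype_diversity(
    panel: HaplotypePanel, region: Region, mode: str = "sample_corrected"
) -> float:
    """Multi-SNP haplotype diversity H of a region.

    With f_i the observed frequencies of the distinct haplotypes over the
    region's SNPs, H = k/(k-1) * (1 - sum f_i^2).  Mode ``sample_corrected``
    (default) uses k = N, the number of haplotypes, which guarantees
    H in [0, 1].  Mode ``snp_count`` uses k = m, the number of SNPs in the
    region; this variant can exceed 1 (e.g. m = 2 with four equally frequent
    haplotypes gives 1.5) and a warning is emitted when it does.
    """
    if mode not in ("sample_corrected", "snp_count"):
        raise LdError(f"unknown diversity mode {mode!r}")
    X = panel.alleles[:, region.snp_indices]
    N = X.shape[0]
    m = X.shape[1]
    if N < 2 or m < 2:
        raise LdError("haplotype diversity needs N >= 2 haplotypes, m >= 2 SNPs")
    _, counts = np.unique(X, axis=0, return_counts=True)
    f = counts / N
    gini = 1.0 - float((f * f).sum())
    if mode == "sample_corrected":
        return N / (N - 1) * gini
    H = m / (m - 1) * gini
    if H > 1.0:
        warnings.warn(
            f"snp_count haplotype diversity {H:.4f} exceeds 1 "
            f"(m={m}, N={N}); the sample_corrected mode stays in [0, 1]",
            RuntimeWarning,
            stacklevel=2,
        )
    return H


def summarize_region(
    pairs: list[LdPair],
    panel: HaplotypePanel,
    region: Region,
    diversity_mode: str = "sample_corrected",
) -> RegionLdSummary:
    """Medians/means of pairwise r^2 and r^2_s plus haplotype diversity.

    The even-count median is the midpoint of the two central order
    statistics.
    """
    if not pairs:
        raise LdError("summarize_region needs at least one pair")
    r2 = np.array([p.r2 for p in pairs])
    r2s = np.array([p.r2_s for p in pairs])
    return RegionLdSummary(
        region=region,
        n_pairs=len(pairs),
        median_r2=float(np.median(r2)),
        median_r2s=float(np.median(r2s)),
        mean_r2=float(r2.mean()),
        mean_r2s=float(r2s.mean()),
        H=haplotype_diversity(panel, region, mode=diversity_mode),
    )


def summarize_region_fast(
    panel: HaplotypePanel,
    region: Region,
    mmap: MarkerMap,
    diversity_mode: str = "sample_corrected",
) -> RegionLdSummary:
    """Array-path equivalent of pairwise_ld + summarize_region (no per-pair
    Python objects); used by the pipeline on many regions."""
    idx = region.snp_indices
    if idx.size < 2:
        raise LdError("region needs at least 2 SNPs")
    X = panel.alleles[:, idx].astype(float)
    flip = X.mean(axis=0) > 0.5
    X[:, flip] = 1 - X[:, flip]
    p, R2 = _pairwise_r2_matrix(X)
    iu, ju = np.triu_indices(idx.size, k=1)
    pmin = np.minimum(p[iu], p[ju])
    pmax = np.maximum(p[iu], p[ju])
    r2max = (pmin * (1 - pmax)) / ((1 - pmin) * pmax)
    r2 = R2[iu, ju]
    r2s = np.clip(r2 / r2max, 0.0, 1.0)
    return RegionLdSummary(
        region=region,
        n_pairs=int(iu.size),
        median_r2=float(np.median(r2)),
        median_r2s=float(np.median(r2s)),
        mean_r2=float(r2.mean()),
        mean_r2s=float(r2s.mean()),
        H=haplotype_diversity(panel, region, mode=diversity_mode),
    )


def decay_profile(
    pairs: list[LdPair],
    trim_upper_fraction: float = 0.01,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Distance-binned mean LD after trimming the most distant pairs.

    Pairs above the (1 - trim) empirical distance quantile (linear
    interpolation) are dropped — the far tail is sparse and noisy — and the
    rest are binned into ``n_bins`` equal-width distance bins.
    """
    if not pairs:
        raise LdError("decay_profile needs at least one pair")
    dist = np.array([p.distance for p in pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs])
    r2s = np.array([p.r2_s for p in pairs])
    if trim_upper_fraction > 0:
        cut = np.quantile(dist, 1.0 - trim_upper_fraction, method="linear")
        keep = dist <= cut
        dist, r2, r2s = dist[keep], r2[keep], r2s[keep]
    lo, hi = dist.min(), dist.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_mid": 0.5 * (edges[b] + edges[b + 1]),
                "mean_r2": float(r2[mask].mean()),
                "mean_r2s": float(r2s[mask].mean()),
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
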