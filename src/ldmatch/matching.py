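"""Best-matching control window selection for reference SNP sets.

For each genic reference set of m SNPs, every run of >= m consecutive
non-genic SNPs contributes sliding windows of m SNPs as candidate control
sets.  Candidates are compared to the reference on three characteristics
known to bias LD measures: the MAFs, the pairwise absolute MAF differences
(delta) and the pairwise physical distances (PWD).  For each characteristic
the area between the two ECDFs (the 1-Wasserstein distance) is computed;
candidates are ranked per characteristic (smallest area = rank 1, ties take
the minimum rank) and the candidate with the smallest rank sum T wins.
A second, non-overlapping control matched to the first one serves as the
negative control.  References with too few SNPs or too few candidates are
excluded — similarity of the best match cannot be assured there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .genotype_io import MarkerMap
from .regions import Region


class MatchingError(ValueError):
    """Raised for invalid matching inputs."""


@dataclass
class CharacteristicSamples:
    """The three matching characteristics of one SNP set: per-SNP MAFs,
    pairwise |MAF_i - MAF_j| and pairwise physical distances (all unordered
    multisets held as arrays)."""

    mafs: np.ndarray
    maf_diffs: np.ndarray
    pair_distances: np.ndarray


@dataclass
class MatchScore:
    """Wasserstein areas of one candidate against the reference, the
    per-characteristic ranks among all candidates, and the total rank sum."""

    a_maf: float
    a_delta: float
    a_pwd: float
    rank_maf: int = 0
    rank_delta: int = 0
    rank_pwd: int = 0
    total: int = 0


@dataclass
class ExclusionRecord:
    """A reference set dropped from the analysis, with the reason."""

    chromosome: str
    span: tuple[int, int] | None
    n_snps: int
    reason: str
    n_candidates: int = 0


@dataclass
class MatchedTriple:
    """A reference set with its matched control and negative control."""

    G: Region
    IG: Region
    IG_prime: Region
    score_IG: MatchScore
    score_IG_prime: MatchScore
    n_candidates: int
    n_candidates_ig_prime: int = 0


def ecdf_area(sample_a, sample_b) -> float:
    """Area between the ECDFs of two samples (1-Wasserstein distance),
    computed as the step-function integral of |F_A - F_B| over the pooled
    range.  For equal-size samples this equals the mean absolute difference
    of sorted order statistics (that identity is used as a test oracle, not
    here)."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise MatchingError("ecdf_area requires non-empty samples")
    pts = np.concatenate([a, b])
    pts.sort(kind="stable")
    dx = np.diff(pts)
    fa = np.searchsorted(a, pts[:-1], side="right") / a.size
    fb = np.searchsorted(b, pts[:-1], side="right") / b.size
    return float(np.sum(np.abs(fa - fb) * dx))


def characteristic_samples(region: Region, mmap: MarkerMap) -> CharacteristicSamples:
    """MAFs, pairwise MAF differences and pairwise distances of a region."""
    idx = region.snp_indices
    if idx.size < 2:
        raise MatchingError("characteristics need a region with >= 2 SNPs")
    maf = mmap.maf[idx]
    pos = mmap.pos[idx]
    iu, ju = np.triu_indices(idx.size, k=1)
    return CharacteristicSamples(
        mafs=maf.copy(),
        maf_diffs=np.abs(maf[iu] - maf[ju]),
        pair_distances=np.abs(pos[iu] - pos[ju]).astype(float),
    )


def candidate_windows(
    nongenic_segments: list[Region], window_size: int, step: int = 1
) -> list[Region]:
    """Sliding windows of ``window_size`` consecutive non-genic SNPs.

    Each segment of length L contributes the windows starting at offsets
    0, step, 2*step, ... while L - offset >= window_size; windows never span
    a genic region or a chromosome break because segments never do.
    Ordering is genomic.
    """
    if window_size < 2:
        raise MatchingError("window_size must be >= 2")
    out: list[Region] = []
    for seg in nongenic_segments:
        idx = seg.snp_indices
        for start in range(0, idx.size - window_size + 1, step):
            win = idx[start : start + window_size]
            out.append(
                Region(
                    chromosome=seg.chromosome,
                    snp_indices=win,
                    label="candidate",
                )
            )
    return out


def _rank_and_total(areas: np.ndarray) -> list[MatchScore]:
    """Per-characteristic minimum ranks and rank-sum totals for an
    (n_candidates, 3) area matrix."""
    ranks = np.column_stack(
        [rankdata(areas[:, k], method="min") for k in range(3)]
    ).astype(int)
    totals = ranks.sum(axis=1)
    return [
        MatchScore(
            a_maf=float(areas[i, 0]),
            a_delta=float(areas[i, 1]),
            a_pwd=float(areas[i, 2]),
            rank_maf=int(ranks[i, 0]),
            rank_delta=int(ranks[i, 1]),
            rank_pwd=int(ranks[i, 2]),
            total=int(totals[i]),
        )
        for i in range(areas.shape[0])
    ]


def score_candidates(
    reference: CharacteristicSamples, candidates: list[CharacteristicSamples]
) -> list[MatchScore]:
    """Wasserstein areas of each candidate against the reference for all
    three characteristics, with per-characteristic minimum ranks and the
    rank-sum total T."""
    if not candidates:
        raise MatchingError("score_candidates needs at least one candidate")
    areas = np.array(
        [
            [
                ecdf_area(reference.mafs, c.mafs),
                ecdf_area(reference.maf_diffs, c.maf_diffs),
                ecdf_area(reference.pair_distances, c.pair_distances),
            ]
            for c in candidates
        ]
    )
    return _rank_and_total(areas)


def _select_best(
    candidates: list[Region], scores: list[MatchScore]
) -> tuple[Region, MatchScore]:
    """Minimal total, ties broken by smaller a_maf, a_delta, a_pwd, then
    leftmost genomic position (candidate list is in genomic order)."""
    totals = np.array([s.total for s in scores])
    tie = np.flatnonzero(totals == totals.min())
    keys = np.lexsort(
        (
            tie,  # genomic order as final tie-break
            np.array([scores[i].a_pwd for i in tie]),
            np.array([scores[i].a_delta for i in tie]),
            np.array([scores[i].a_maf for i in tie]),
        )
    )
    best = int(tie[keys[0]])
    return candidates[best], scores[best]


def best_match(
    reference: Region,
    candidates: list[Region],
    mmap: MarkerMap,
    excluded_snp_indices: frozenset | set = frozenset(),
    min_candidates: int = 50,
) -> tuple[Region, MatchScore] | ExclusionRecord:
    """Best-matching candidate window for a reference set.

    Candidates sharing any SNP with ``excluded_snp_indices`` are removed
    first; if fewer than ``min_candidates`` remain the reference is excluded
    (a recorded outcome, not an error).
    """
    if excluded_snp_indices:
        excl = np.fromiter(excluded_snp_indices, dtype=np.int64)
        candidates = [
            c for c in candidates if not np.isin(c.snp_indices, excl).any()
        ]
    if len(candidates) < min_candidates:
        return ExclusionRecord(
            chromosome=reference.chromosome,
            span=reference.span,
            n_snps=reference.n_snps,
            reason="too few candidates",
            n_candidates=len(candidates),
        )
    ref_chars = characteristic_samples(reference, mmap)
    scores = score_candidates(
        ref_chars, [characteristic_samples(c, mmap) for c in candidates]
    )
    region, score = _select_best(candidates, scores)
    return region, score


# ---------------------------------------------------------------------------
# Batch engine for whole-genome matching
# ---------------------------------------------------------------------------
#
# Reference and candidate windows always have the same SNP count, so all
# three characteristic samples are equal-size and the Wasserstein area
# reduces exactly to the mean absolute difference of sorted order statistics.
# Window characteristics depend only on (search domain, window size), so they
# are computed once per such pair and reused across references — including
# the negative-control pass.


@dataclass
class _WindowSet:
    """Precomputed candidate windows of one size on one search domain.
    Row k of ``W`` holds the SNP column indices of window k (windows are
    contiguous runs within a single non-genic segment, in genomic order,
    identical to :func:`candidate_windows` output)."""

    W: np.ndarray  # (n_windows, m) SNP column indices
    chrom: np.ndarray  # per-window chromosome (object)
    sorted_maf: np.ndarray  # (n_windows, m)
    sorted_delta: np.ndarray  # (n_windows, m(m-1)/2)
    sorted_pwd: np.ndarray  # (n_windows, m(m-1)/2)

    @property
    def n_windows(self) -> int:
        return self.W.shape[0]

    def region(self, k: int, mmap: MarkerMap, label: str) -> Region:
        idx = self.W[k]
        return Region(
            chromosome=str(self.chrom[k]), snp_indices=idx, label=label,
            span=(int(mmap.pos[idx[0]]), int(mmap.pos[idx[-1]])),
        )


def _build_window_set(
    segments: list[Region], m: int, mmap: MarkerMap, step: int
) -> _WindowSet:
    blocks = []
    chroms = []
    for seg in segments:
        idx = seg.snp_indices
        if idx.size < m:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(idx, m)[::step]
        blocks.append(wins)
        chroms.extend([seg.chromosome] * wins.shape[0])
    if not blocks:
        return _WindowSet(
            W=np.empty((0, m), np.int64), chrom=np.empty(0, dtype=object),
            sorted_maf=np.empty((0, m)),
            sorted_delta=np.empty((0, m * (m - 1) // 2)),
            sorted_pwd=np.empty((0, m * (m - 1) // 2)),
        )
    W = np.ascontiguousarray(np.concatenate(blocks, axis=0))
    iu, ju = np.triu_indices(m, k=1)
    maf = mmap.maf[W]
    pos = mmap.pos[W].astype(float)
    return _WindowSet(
        W=W,
        chrom=np.array(chroms, dtype=object),
        sorted_maf=np.sort(maf, axis=1),
        sorted_delta=np.sort(np.abs(maf[:, iu] - maf[:, ju]), axis=1),
        sorted_pwd=np.sort(np.abs(pos[:, iu] - pos[:, ju]), axis=1),
    )


def _batch_areas(ws: _WindowSet, ref: CharacteristicSamples, keep: np.ndarray) -> np.ndarray:
    """Equal-size Wasserstein areas of every kept window against the
    reference: mean |sorted ref - sorted window| per characteristic."""
    a = np.abs(ws.sorted_maf[keep] - np.sort(ref.mafs)).mean(axis=1)
    d = np.abs(ws.sorted_delta[keep] - np.sort(ref.maf_diffs)).mean(axis=1)
    p = np.abs(ws.sorted_pwd[keep] - np.sort(ref.pair_distances)).mean(axis=1)
    return np.column_stack([a, d, p])


def _best_from_areas(
    ws: _WindowSet, keep_idx: np.ndarray, areas: np.ndarray,
    mmap: MarkerMap, label: str,
) -> tuple[Region, MatchScore]:
    ranks = np.column_stack(
        [rankdata(areas[:, k], method="min") for k in range(3)]
    ).astype(int)
    totals = ranks.sum(axis=1)
    tie = np.flatnonzero(totals == totals.min())
    order = np.lexsort((tie, areas[tie, 2], areas[tie, 1], areas[tie, 0]))
    b = int(tie[order[0]])
    score = MatchScore(
        a_maf=float(areas[b, 0]), a_delta=float(areas[b, 1]),
        a_pwd=float(areas[b, 2]), rank_maf=int(ranks[b, 0]),
        rank_delta=int(ranks[b, 1]), rank_pwd=int(ranks[b, 2]),
        total=int(totals[b]),
    )
    return ws.region(int(keep_idx[b]), mmap, label), score


def select_matched_triples(
    eligible: list[Region],
    mmap: MarkerMap,
    nongenic_segments: list[Region],
    min_candidates: int = 50,
    step: int = 1,
    pool: dict | None = None,
) -> tuple[list[MatchedTriple], list[ExclusionRecord]]:
    """Matched control (IG) and negative control (IG') for every eligible
    reference set.

    The candidate search domain of a reference is its own chromosome, or the
    pooled group of chromosomes ``pool`` maps that chromosome to (used for
    genomes whose small chromosomes carry too few candidates on their own;
    windows still never cross a chromosome break).  IG is the best-matching
    window for G; IG' is the best match for IG among windows sharing no SNP
    with IG.  Either step failing the candidate-count rule excludes the
    reference.  Different references may receive overlapping controls.
    """
    pool = pool or {}
    seg_by_domain: dict = {}
    for seg in nongenic_segments:
        dom = pool.get(seg.chromosome, seg.chromosome)
        seg_by_domain.setdefault(dom, []).append(seg)

    cache: dict[tuple, _WindowSet] = {}
    triples: list[MatchedTriple] = []
    exclusions: list[ExclusionRecord] = []

    for G in eligible:
        dom = pool.get(G.chromosome, G.chromosome)
        m = G.n_snps
        key = (dom, m)
        if key not in cache:
            cache[key] = _build_window_set(
                seg_by_domain.get(dom, []), m, mmap, step
            )
        ws = cache[key]
        n_cand = ws.n_windows
        if n_cand < min_candidates:
            exclusions.append(
                ExclusionRecord(
                    chromosome=G.chromosome, span=G.span, n_snps=m,
                    reason="too few candidates", n_candidates=n_cand,
                )
            )
            continue
        all_idx = np.arange(n_cand)
        ref_chars = characteristic_samples(G, mmap)
        IG, ig_score = _best_from_areas(
            ws, all_idx, _batch_areas(ws, ref_chars, all_idx), mmap, "IG"
        )

        # negative control: windows overlapping IG (contiguous index run)
        # are removed before scoring
        overlap = (
            (ws.chrom == IG.chromosome)
            & (ws.W[:, 0] <= IG.snp_indices[-1])
            & (ws.W[:, -1] >= IG.snp_indices[0])
        )
        keep_idx = np.flatnonzero(~overlap)
        if keep_idx.size < min_candidates:
            exclusions.append(
                ExclusionRecord(
                    chromosome=G.chromosome, span=G.span, n_snps=m,
                    reason="too few candidates for negative control",
                    n_candidates=int(keep_idx.size),
                )
            )
            continue
        ig_chars = characteristic_samples(IG, mmap)
        IG_prime, igp_score = _best_from_areas(
            ws, keep_idx, _batch_areas(ws, ig_chars, keep_idx), mmap,
            "IG_prime",
        )
        triples.append(
            MatchedTriple(
                G=G, IG=IG, IG_prime=IG_prime,
                score_IG=ig_score, score_IG_prime=igp_score,
                n_candidates=n_cand,
                n_candidates_ig_prime=int(keep_idx.size),
            )
        )
    return triples, exclusions
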