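"""ECDF-area matching, candidate windows and control-set selection."""

import numpy as np
import pytest

from ldmatch import (
    Region,
    best_match,
    candidate_windows,
    characteristic_samples,
    ecdf_area,
    score_candidates,
    select_matched_triples,
)
from ldmatch.genotype_io import MarkerMap
from ldmatch.matching import (
    ExclusionRecord,
    MatchingError,
    _batch_areas,
    _build_window_set,
)

from conftest import make_map


def _sorted_mean_abs_diff(a, b):
    """Independent equal-size Wasserstein oracle."""
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


class TestEcdfArea:
    def test_identical_multisets_zero(self, rng):
        a = rng.random(17)
        assert ecdf_area(a, a.copy()) == pytest.approx(0.0)

    def test_unit_step_separation(self):
        assert ecdf_area([0.0], [1.0]) == pytest.approx(1.0)

    def test_interleaved_step_integral(self):
        # |F_A - F_B| is 1/2 on [0,1], 0 on [1,2], 1/2 on [2,3] -> area 1
        assert ecdf_area([0, 2], [1, 3]) == pytest.approx(1.0)
        assert _sorted_mean_abs_diff([0, 2], [1, 3]) == pytest.approx(1.0)

    def test_equal_size_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            a, b = rng.random(n) * 10, rng.random(n) * 10
            assert ecdf_area(a, b) == pytest.approx(
                _sorted_mean_abs_diff(a, b), abs=1e-9
            )

    def test_unequal_sizes_supported(self):
        # F_A jumps to 1 at 0; F_B jumps 1/2 at 1, 1 at 3
        # area = 1*1 + 0.5*2 ... over [0,1] |1-0|=1, [1,3] |1-0.5|=0.5
        assert ecdf_area([0.0], [1.0, 3.0]) == pytest.approx(2.0)

    def test_metric_axioms(self, rng):
        for _ in range(30):
            a, b, c = (rng.random(8) for _ in range(3))
            dab = ecdf_area(a, b)
            assert dab == pytest.approx(ecdf_area(b, a))
            assert dab >= 0
            assert dab <= ecdf_area(a, c) + ecdf_area(c, b) + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(MatchingError):
            ecdf_area([], [1.0])


class TestCandidateWindows:
    def _segments(self, sizes):
        segs, start = [], 0
        for n in sizes:
            segs.append(
                Region("chr1", np.arange(start, start + n), "non_genic_segment")
            )
            start += n + 10
        return segs

    @pytest.mark.parametrize(
        "sizes,m,expected",
        [
            ([12], 10, 3),
            ([5, 5], 10, 0),  # windows never span segments
            ([60, 9, 31], 10, 51 + 0 + 22),
        ],
    )
    def test_window_counts(self, sizes, m, expected):
        assert len(candidate_windows(self._segments(sizes), m)) == expected

    def test_step_subsamples_windows(self):
        wins = candidate_windows(self._segments([20]), 10, step=5)
        assert len(wins) == 3  # offsets 0, 5, 10

    def test_engine_windows_match_public_op(self):
        segs = self._segments([15, 8, 23])
        mmap = make_map(np.arange(1, 100) * 10)
        ws = _build_window_set(segs, 7, mmap, step=1)
        public = candidate_windows(segs, 7)
        assert ws.n_windows == len(public)
        for k, win in enumerate(public):
            np.testing.assert_array_equal(ws.W[k], win.snp_indices)


class TestCharacteristicSamples:
    def test_enumerated_example(self):
        mmap = make_map([100, 200, 500], maf=np.array([0.1, 0.2, 0.4]))
        cs = characteristic_samples(Region("chr1", [0, 1, 2], "G"), mmap)
        assert sorted(cs.maf_diffs.tolist()) == pytest.approx([0.1, 0.2, 0.3])
        assert sorted(cs.pair_distances.tolist()) == [100, 300, 400]

    def test_sizes(self):
        mmap = make_map(np.arange(1, 11) * 100)
        cs = characteristic_samples(Region("chr1", np.arange(10), "G"), mmap)
        assert cs.mafs.size == 10
        assert cs.maf_diffs.size == 45
        assert cs.pair_distances.size == 45


class TestScoreCandidates:
    def test_identical_candidate_minimal_score(self, rng):
        mmap = make_map(
            np.arange(1, 21) * 100, maf=rng.uniform(0.05, 0.5, 20)
        )
        ref = characteristic_samples(Region("chr1", np.arange(5), "G"), mmap)
        cands = [
            characteristic_samples(
                Region("chr1", np.arange(s, s + 5), "C"), mmap
            )
            for s in (5, 10)
        ]
        cands.append(ref)  # verbatim copy present
        scores = score_candidates(ref, cands)
        assert scores[-1].a_maf == scores[-1].a_delta == scores[-1].a_pwd == 0.0
        assert scores[-1].total == 3

    def test_single_candidate_total_three(self, rng):
        mmap = make_map(np.arange(1, 11) * 100, maf=rng.uniform(0.05, 0.5, 10))
        ref = characteristic_samples(Region("chr1", np.arange(4), "G"), mmap)
        cand = characteristic_samples(Region("chr1", np.arange(4, 8), "C"), mmap)
        (s,) = score_candidates(ref, [cand])
        assert (s.rank_maf, s.rank_delta, s.rank_pwd, s.total) == (1, 1, 1, 3)

    def test_ranks_match_sort_oracle(self, rng):
        mmap = make_map(
            np.sort(rng.choice(np.arange(1, 10000), 60, replace=False)),
            maf=rng.uniform(0.02, 0.5, 60),
        )
        ref = characteristic_samples(Region("chr1", np.arange(6), "G"), mmap)
        cands = [
            characteristic_samples(
                Region("chr1", np.arange(s, s + 6), "C"), mmap
            )
            for s in range(6, 51, 9)
        ]
        scores = score_candidates(ref, cands)
        for key, attr in [
            ("a_maf", "rank_maf"), ("a_delta", "rank_delta"), ("a_pwd", "rank_pwd"),
        ]:
            areas = np.array([getattr(s, key) for s in scores])
            # minimum-rank convention oracle
            expected = [1 + int((areas < a).sum()) for a in areas]
            assert [getattr(s, attr) for s in scores] == expected
        for s in scores:
            assert s.total == s.rank_maf + s.rank_delta + s.rank_pwd


class TestBestMatch:
    def _setup(self, rng, n_nongenic=120, m=5):
        pos = np.sort(rng.choice(np.arange(1, 50_000), n_nongenic + m, False))
        maf = rng.uniform(0.02, 0.5, n_nongenic + m)
        mmap = make_map(pos, maf=maf)
        ref = Region("chr1", np.arange(m), "G")
        seg = Region("chr1", np.arange(m, m + n_nongenic), "non_genic_segment")
        return mmap, ref, seg

    def test_too_few_candidates_is_exclusion_record(self, rng):
        mmap, ref, seg = self._setup(rng, n_nongenic=53, m=5)  # 49 windows
        cands = candidate_windows([seg], 5)
        assert len(cands) == 49
        out = best_match(ref, cands, mmap, min_candidates=50)
        assert isinstance(out, ExclusionRecord)
        assert out.reason == "too few candidates"
        assert out.n_candidates == 49

    def test_planted_copy_wins_with_total_three(self, rng):
        # copy the reference characteristics verbatim into the pool:
        # same MAFs, positions shifted by a constant (distances preserved)
        m = 6
        ref_pos = np.array([100, 340, 560, 700, 1200, 1210])
        ref_maf = rng.uniform(0.05, 0.5, m)
        pool_pos = np.sort(rng.choice(np.arange(5000, 40000), 80, False))
        copy_pos = ref_pos + 50_000
        pos = np.concatenate([ref_pos, pool_pos, copy_pos])
        maf = np.concatenate([ref_maf, rng.uniform(0.02, 0.5, 80), ref_maf])
        mmap = make_map(pos, maf=maf)
        ref = Region("chr1", np.arange(m), "G")
        seg = Region("chr1", np.arange(m, len(pos)), "non_genic_segment")
        cands = candidate_windows([seg], m)
        region, score = best_match(ref, cands, mmap, min_candidates=1)
        assert (score.a_maf, score.a_delta, score.a_pwd) == (0.0, 0.0, 0.0)
        assert score.total == 3
        np.testing.assert_array_equal(
            region.snp_indices, np.arange(len(pos) - m, len(pos))
        )

    def test_tie_break_prefers_smaller_maf_area(self):
        # equal totals by construction: c1 wins the MAF rank, c2 wins the
        # delta rank (its MAFs are the reference's shifted by a constant, so
        # its pairwise differences match exactly), PWD ties at 0 for both;
        # the tie then falls to the smaller a_maf, i.e. c1
        mmap = make_map(
            np.arange(1, 16) * 100,
            maf=np.array(
                [0.10, 0.20, 0.30, 0.40, 0.50,  # reference
                 0.10, 0.20, 0.30, 0.40, 0.45,  # closest MAFs, distorted deltas
                 0.05, 0.15, 0.25, 0.35, 0.45]  # shifted: exact deltas
            ),
        )
        ref = Region("chr1", np.arange(5), "G")
        c1 = Region("chr1", np.arange(5, 10), "C")
        c2 = Region("chr1", np.arange(10, 15), "C")
        scores = score_candidates(
            characteristic_samples(ref, mmap),
            [characteristic_samples(c, mmap) for c in (c2, c1)],
        )
        assert scores[0].total == scores[1].total  # genuine tie
        region, score = best_match(ref, [c2, c1], mmap, min_candidates=1)
        np.testing.assert_array_equal(region.snp_indices, c1.snp_indices)
        assert score.a_maf == pytest.approx(0.01)

    def test_excluded_snps_filtered_before_scoring(self, rng):
        mmap, ref, seg = self._setup(rng, n_nongenic=60, m=5)
        cands = candidate_windows([seg], 5)
        excluded = set(cands[0].snp_indices.tolist())
        out = best_match(
            ref, cands, mmap, excluded_snp_indices=excluded, min_candidates=1
        )
        region, _ = out
        assert not (set(region.snp_indices.tolist()) & excluded)


class TestSelectMatchedTriples:
    def _toy(self, rng, n_gene=10, n_nongenic=200):
        total = n_gene + n_nongenic
        pos = np.sort(rng.choice(np.arange(1, 10**6), total, False))
        mmap = make_map(pos, maf=rng.uniform(0.02, 0.5, total))
        G = Region("chr1", np.arange(n_gene), "G")
        seg = Region(
            "chr1", np.arange(n_gene, total), "non_genic_segment"
        )
        return mmap, G, seg

    def test_single_gene_window_count(self, rng):
        mmap, G, seg = self._toy(rng)
        triples, excl = select_matched_triples([G], mmap, [seg])
        assert len(triples) == 1 and not excl
        assert triples[0].n_candidates == 191  # 200 - 10 + 1

    def test_triple_invariants(self, rng):
        mmap, G, seg = self._toy(rng)
        (t,) = select_matched_triples([G], mmap, [seg])[0]
        assert t.IG.n_snps == t.G.n_snps == t.IG_prime.n_snps
        ig = set(t.IG.snp_indices.tolist())
        igp = set(t.IG_prime.snp_indices.tolist())
        assert not ig & igp
        nongenic = set(seg.snp_indices.tolist())
        assert ig <= nongenic and igp <= nongenic

    def test_engine_agrees_with_best_match(self, rng):
        mmap, G, seg = self._toy(rng, n_gene=6, n_nongenic=80)
        (t,) = select_matched_triples([G], mmap, [seg])[0]
        cands = candidate_windows([seg], 6)
        region, score = best_match(G, cands, mmap, min_candidates=1)
        np.testing.assert_array_equal(t.IG.snp_indices, region.snp_indices)
        assert t.score_IG.total == score.total
        assert t.score_IG.a_maf == pytest.approx(score.a_maf, abs=1e-12)
        assert t.score_IG.a_pwd == pytest.approx(score.a_pwd, abs=1e-9)

    def test_small_gene_goes_to_exclusion_log(self, rng):
        mmap, G, seg = self._toy(rng, n_gene=10, n_nongenic=30)  # 21 windows
        triples, excl = select_matched_triples([G], mmap, [seg])
        assert not triples
        assert excl[0].reason == "too few candidates"

    def test_pooled_chromosome_search_domain(self, rng):
        # gene on chr1; candidate windows only available on chr2 via pooling
        pos1 = np.arange(1, 11) * 100
        pos2 = np.arange(1, 101) * 100
        chrom = np.array(["chr1"] * 10 + ["chr2"] * 100, dtype=object)
        mmap = MarkerMap(
            chrom=chrom,
            pos=np.concatenate([pos1, pos2]),
            maf=rng.uniform(0.05, 0.5, 110),
        )
        G = Region("chr1", np.arange(10), "G")
        seg = Region("chr2", np.arange(10, 110), "non_genic_segment")
        none, excl = select_matched_triples([G], mmap, [seg])
        assert not none and excl[0].n_candidates == 0
        pool = {"chr1": "d0", "chr2": "d0"}
        triples, _ = select_matched_triples([G], mmap, [seg], pool=pool)
        assert len(triples) == 1
        assert triples[0].IG.chromosome == "chr2"
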