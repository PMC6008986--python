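"""Local alignment vs an independent affine-gap DP oracle, complementary
segment recovery, seed extraction, and MRE site finding."""

import numpy as np
import pytest

from regchar.io_core import SequenceRecord, ValidationError, reverse_complement
from regchar.mre_discovery import (
    AlignmentScoring,
    extract_seed,
    find_complementary_segment,
    find_mre,
    local_align,
    mir_similarity_search,
)
from regchar.synthetic_data import gen_convergent_pair


def gotoh_local_score(a, b, scoring=AlignmentScoring()):
    """Independent Smith-Waterman affine-gap oracle (score only).

    Gap of length L costs gap_open + gap_extend * L; local optima never end
    in a gap, so the best M-state cell is the optimum.
    """
    neg = float("-inf")
    open_cost = scoring.gap_open + scoring.gap_extend
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scoring.match if a[i - 1] == b[j - 1] else scoring.mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - open_cost, Ix[i - 1][j] - scoring.gap_extend)
            Iy[i][j] = max(M[i][j - 1] - open_cost, Iy[i][j - 1] - scoring.gap_extend)
            best = max(best, M[i][j])
    return best


class TestLocalAlign:
    def test_identical_sequences(self):
        res = local_align("ACGT", "ACGT")
        assert res.score == 20 and res.identity_percent == 100.0
        assert res.alignment_length == 4

    def test_single_mismatch_example(self):
        res = local_align("ACGTACGT", "ACGAACGT")
        assert res.score == 31
        assert (res.matches, res.alignment_length) == (7, 8)
        assert res.identity_percent == pytest.approx(87.5)
        assert res.rescore(AlignmentScoring()) == res.score

    def test_no_positive_pair_is_none(self):
        assert local_align("AAAA", "CCCC") is None

    def test_score_equals_dp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 30))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 30))))
            res = local_align(a, b)
            got = res.score if res else 0.0
            assert got == gotoh_local_score(a, b)

    def test_symmetry_for_symmetric_scoring(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=20))
            b = "".join(rng.choice(list("ACGT"), size=20))
            ra, rb = local_align(a, b), local_align(b, a)
            assert (ra.score if ra else 0) == (rb.score if rb else 0)

    def test_identity_recomputable_from_aligned_strings(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=25))
            b = "".join(rng.choice(list("ACGT"), size=25))
            res = local_align(a, b)
            if res is None:
                continue
            matches = sum(
                1 for x, y in zip(res.aligned_a, res.aligned_b) if x == y and x != "-"
            )
            assert res.identity_percent == pytest.approx(
                100 * matches / len(res.aligned_a)
            )
            # ungapping reproduces the claimed source substrings
            assert res.aligned_a.replace("-", "") == a[res.a_start - 1 : res.a_end]
            assert res.aligned_b.replace("-", "") == b[res.b_start - 1 : res.b_end]


class TestComplementarySegment:
    def test_exact_reverse_complement_pair(self):
        a = SequenceRecord("a", "AAACCC")
        b = SequenceRecord("b", "GGGTTT")
        res = find_complementary_segment(a, b, min_length=6, min_identity=100)
        assert res.alignment_length == 6 and res.identity_percent == 100.0
        assert (res.b_start, res.b_end) == (1, 6)

    def test_synthetic_pair_recovers_planted_geometry(self):
        a, b, truth = gen_convergent_pair(seed=11)
        res = find_complementary_segment(a, b)
        assert res.alignment_length == 52
        assert res.identity_percent == pytest.approx(75.0)
        assert res.a_start == truth.position
        assert res.a_end == truth.position + truth.length - 1

    def test_perfect_identity_short_segment(self):
        a, b, _ = gen_convergent_pair(len_a=200, len_b=100, seg_len=30, identity=1.0, seed=5)
        res = find_complementary_segment(a, b)
        assert res.alignment_length == 30 and res.identity_percent == 100.0

    def test_unrelated_flank_alphabets_give_none(self):
        a = SequenceRecord("a", "A" * 100)
        b = SequenceRecord("b", "C" * 100)
        assert find_complementary_segment(a, b) is None

    def test_argument_order_mirrors_coordinates(self):
        a, b, _ = gen_convergent_pair(len_a=300, len_b=150, seg_len=40, identity=0.9, seed=2)
        ab = find_complementary_segment(a, b)
        ba = find_complementary_segment(b, a)
        assert (ab.a_start, ab.a_end) == (ba.b_start, ba.b_end)
        assert (ab.b_start, ab.b_end) == (ba.a_start, ba.a_end)
        assert ab.identity_percent == pytest.approx(ba.identity_percent)


class TestSeedAndMre:
    def test_seed_is_positions_2_to_8(self):
        mir = SequenceRecord("mir", "ACGUACGUACGUACGUACGUAC", "RNA")
        assert extract_seed(mir) == "CGUACGU"
        assert extract_seed(mir, first=1, last=8) == "ACGUACGU"

    def test_short_mir_rejected(self):
        with pytest.raises(ValidationError):
            extract_seed(SequenceRecord("m", "ACGUAC", "RNA"))

    def test_planted_site_found_at_expected_position(self):
        mir = SequenceRecord("mir", "UAGCUAGCUAGCUAGCUAGCUA", "RNA")
        seed = extract_seed(mir)  # AGCUAGC
        site = reverse_complement(seed.replace("U", "T"))
        utr = SequenceRecord("utr", "A" * 30 + site + "A" * 30)
        hits = find_mre(utr, mir)
        assert len(hits) == 1
        assert hits[0].utr_position == 31
        assert hits[0].match_type == "seed7_exact"
        assert hits[0].seed == seed

    def test_mismatch_threshold_behavior(self):
        mir = SequenceRecord("mir", "UAGCUAGCUAGCUAGCUAGCUA", "RNA")
        site = list(reverse_complement(extract_seed(mir).replace("U", "T")))
        site[3] = "A" if site[3] != "A" else "G"
        utr = SequenceRecord("utr", "C" * 20 + "".join(site) + "C" * 20)
        assert find_mre(utr, mir, max_seed_mismatches=0) == []
        hits = find_mre(utr, mir, max_seed_mismatches=1)
        assert len(hits) == 1 and hits[0].match_type == "seed7_1mm"

    def test_multiple_planted_sites_all_found(self, rng):
        mir = SequenceRecord("mir", "ACGGUUACGGUUACGGUUACGG", "RNA")
        site = reverse_complement(extract_seed(mir).replace("U", "T"))
        spacer = "A" * 15
        utr = SequenceRecord("utr", spacer + site + spacer + site + spacer)
        hits = find_mre(utr, mir)
        assert [h.utr_position for h in hits] == [16, 16 + len(site) + 15]


class TestMirSimilaritySearch:
    def test_exact_substring_ranks_first(self):
        query = SequenceRecord("q", "GGGG" + "ACGTACGTACGTACGTACGTAC" + "GGGG")
        mature = [
            SequenceRecord("exact", "ACGUACGUACGUACGUACGUAC", "RNA"),
            SequenceRecord("unrelated", "UUUUUUUUUUUUUUUUUUUUUU", "RNA"),
        ]
        ranked = mir_similarity_search(query, mature, top_n=2)
        assert ranked[0][0] == "exact"
        assert ranked[0][1].identity_percent == 100.0

    def test_all_zero_scores_for_disjoint_alphabets(self):
        query = SequenceRecord("q", "A" * 30)
        mature = [SequenceRecord(f"m{i}", "C" * 22, "DNA") for i in range(3)]
        ranked = mir_similarity_search(query, mature, top_n=3)
        assert all(res is None for _, res in ranked)

    def test_ranking_consistent_with_independent_alignments(self, rng):
        query = SequenceRecord("q", "".join(rng.choice(list("ACGT"), size=60)))
        mature = [
            SequenceRecord(f"m{i}", "".join(rng.choice(list("ACGT"), size=22)))
            for i in range(6)
        ]
        ranked = mir_similarity_search(query, mature, top_n=6)
        scores = [res.score if res else 0.0 for _, res in ranked]
        assert scores == sorted(scores, reverse=True)
        expected = {m.id: local_align(query, m) for m in mature}
        for mir_id, res in ranked:
            exp = expected[mir_id]
            assert (res.score if res else 0.0) == (exp.score if exp else 0.0)

    def test_empty_mature_set_rejected(self):
        with pytest.raises(ValidationError):
            mir_similarity_search(SequenceRecord("q", "ACGT"), [])
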