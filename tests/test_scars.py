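"""Scar counters: hand-derived examples, brute-force oracle equivalence,
and structural invariants (idempotent smoothing, monotone event addition,
chromosome-order invariance).
"""

import numpy as np
import pytest

from cdkres.genome import MB, Chromosome, GenomeModel
from cdkres.scars import (
    Seg,
    compute_cin,
    count_hrd_loh,
    count_lst,
    count_tai,
    hrd_index,
    score_sample,
    smooth_segments,
)
from cdkres.simulate import simulate_segments

from oracles import (
    brute_cin,
    brute_hrd_loh,
    brute_lst,
    brute_tai,
    random_profile,
)


@pytest.fixture(scope="module")
def chr100():
    """A single 100 Mb chromosome with centromere at 48-52 Mb."""
    return GenomeModel([Chromosome("1", 100 * MB, 48 * MB, 52 * MB)])


class TestSmoothing:
    def test_adjacent_equal_cn_merged(self):
        segs = [Seg(1, 10 * MB, 1, 1), Seg(10 * MB + 1, 25 * MB, 1, 1)]
        assert smooth_segments(segs) == [Seg(1, 25 * MB, 1, 1)]

    def test_short_segment_removed_and_flanks_bridged(self):
        # 15 Mb (1,1) | 2 Mb (2,1) | 12 Mb (1,1) -> one 29 Mb (1,1) segment
        segs = [
            Seg(1, 15 * MB, 1, 1),
            Seg(15 * MB + 1, 17 * MB, 2, 1),
            Seg(17 * MB + 1, 29 * MB, 1, 1),
        ]
        out = smooth_segments(segs)
        assert out == [Seg(1, 29 * MB, 1, 1)]
        assert out[0].length == 29 * MB

    def test_short_segment_between_different_flanks_dropped(self):
        segs = [
            Seg(1, 15 * MB, 1, 1),
            Seg(15 * MB + 1, 17 * MB, 2, 1),
            Seg(17 * MB + 1, 29 * MB, 2, 2),
        ]
        out = smooth_segments(segs)
        assert out == [Seg(1, 15 * MB, 1, 1), Seg(17 * MB + 1, 29 * MB, 2, 2)]

    def test_idempotent_on_random_profiles(self, genome, rng):
        for _ in range(20):
            prof = random_profile(rng, genome)
            for segs in prof.values():
                once = smooth_segments([Seg(*s) for s in segs])
                assert smooth_segments(once) == once

    def test_empty_input(self):
        assert smooth_segments([]) == []


class TestHrdLoh:
    def test_diploid_genome_zero(self, chr100):
        segs = {"1": [Seg(1, 100 * MB, 1, 1)]}
        assert count_hrd_loh(segs, chr100) == 0

    def test_whole_chromosome_loh_excluded(self, chr100):
        segs = {"1": [Seg(1, 100 * MB, 1, 0)]}
        assert count_hrd_loh(segs, chr100) == 0

    def test_threshold_rule(self, chr100):
        # LOH of 10, 20, 40 Mb -> only the two > 15 Mb count
        segs = {
            "1": [
                Seg(1, 2 * MB, 1, 1),
                Seg(2 * MB + 1, 12 * MB, 1, 0),          # 10 Mb
                Seg(12 * MB + 1, 14 * MB, 1, 1),
                Seg(14 * MB + 1, 34 * MB, 1, 0),         # 20 Mb
                Seg(34 * MB + 1, 36 * MB, 1, 1),
                Seg(36 * MB + 1, 76 * MB, 1, 0),         # 40 Mb
                Seg(76 * MB + 1, 100 * MB, 1, 1),
            ]
        }
        assert count_hrd_loh(segs, chr100) == 2

    def test_homozygous_deletion_does_not_count(self, chr100):
        segs = {"1": [Seg(1, 50 * MB, 0, 0), Seg(50 * MB + 1, 100 * MB, 1, 1)]}
        assert count_hrd_loh(segs, chr100) == 0

    def test_adjacent_loh_segments_count_once(self, chr100):
        segs = {
            "1": [
                Seg(1, 10 * MB, 1, 1),
                Seg(10 * MB + 1, 30 * MB, 1, 0),
                Seg(30 * MB + 1, 45 * MB, 2, 0),
                Seg(45 * MB + 1, 100 * MB, 1, 1),
            ]
        }
        assert count_hrd_loh(segs, chr100) == 1


class TestTai:
    def test_balanced_genome_zero(self, chr100):
        assert count_tai({"1": [Seg(1, 100 * MB, 2, 2)]}, chr100) == 0

    def test_telomeric_ai_counts(self, chr100):
        segs = {"1": [Seg(1, 20 * MB, 2, 1), Seg(20 * MB + 1, 100 * MB, 1, 1)]}
        assert count_tai(segs, chr100) == 1

    def test_centromere_crossing_excluded(self, chr100):
        # AI 40-60 Mb crosses the 48-52 Mb centromere and is interstitial anyway
        segs = {
            "1": [
                Seg(1, 40 * MB - 1, 1, 1),
                Seg(40 * MB, 60 * MB, 2, 1),
                Seg(60 * MB + 1, 100 * MB, 1, 1),
            ]
        }
        assert count_tai(segs, chr100) == 0

    def test_whole_chromosome_ai_excluded(self, chr100):
        assert count_tai({"1": [Seg(1, 100 * MB, 2, 1)]}, chr100) == 0

    def test_min_length(self, chr100):
        segs = {"1": [Seg(1, 10 * MB, 2, 1), Seg(10 * MB + 1, 100 * MB, 1, 1)]}
        assert count_tai(segs, chr100, min_len=11 * MB) == 0
        assert count_tai(segs, chr100, min_len=10 * MB) == 1

    def test_unknown_chromosome_errors(self, chr100):
        with pytest.raises(KeyError):
            count_tai({"7": [Seg(1, 10 * MB, 2, 1)]}, chr100)


class TestLst:
    def test_single_segment_zero(self, chr100):
        assert count_lst({"1": [Seg(1, 100 * MB, 1, 1)]}, chr100) == 0

    def test_contiguous_transition_counts(self, chr100):
        segs = {"1": [Seg(1, 15 * MB, 1, 1), Seg(15 * MB + 1, 27 * MB, 2, 1)]}
        assert count_lst(segs, chr100) == 1

    def test_gap_rule(self, chr100):
        segs = {"1": [Seg(1, 15 * MB, 1, 1), Seg(20 * MB + 1, 32 * MB, 2, 1)]}
        assert count_lst(segs, chr100) == 0  # 5 Mb gap >= 3 Mb

    def test_transition_across_centromere_not_counted(self, chr100):
        # both segments large and contiguous, but the change-point sits at the
        # arm boundary; after splitting, the pieces are on different arms
        segs = {"1": [Seg(1, 50 * MB, 1, 1), Seg(50 * MB + 1, 100 * MB, 2, 1)]}
        assert count_lst(segs, chr100) == 0

    def test_small_segment_blocks_pair(self, chr100):
        segs = {"1": [Seg(1, 15 * MB, 1, 1), Seg(15 * MB + 1, 20 * MB, 2, 1)]}
        assert count_lst(segs, chr100) == 0  # second segment < 10 Mb


class TestHrdIndex:
    def test_zeros(self):
        assert hrd_index(0, 0, 0) == 0

    def test_sum(self):
        assert hrd_index(5, 7, 11) == 23

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hrd_index(-1, 0, 0)


class TestCin:
    def test_uniform_diploid_zero(self):
        assert compute_cin({"1": [Seg(1, 100 * MB, 1, 1)]}) == 0.0

    def test_half_genome_off_mode(self):
        segs = {"1": [Seg(1, 50 * MB, 2, 1), Seg(50 * MB + 1, 100 * MB, 1, 1)]}
        assert compute_cin(segs) == pytest.approx(0.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            compute_cin({})

    def test_matches_brute_force(self, genome, rng):
        for _ in range(20):
            prof = random_profile(rng, genome)
            segs = {c: [Seg(*s) for s in v] for c, v in prof.items()}
            assert compute_cin(segs) == pytest.approx(brute_cin(prof))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_counters_match_brute_force(self, genome, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            prof = random_profile(rng, genome)
            smoothed = {
                c: smooth_segments([Seg(*s) for s in v]) for c, v in prof.items()
            }
            tuples = {c: [(s.start, s.end, s.cn_major, s.cn_minor) for s in v]
                      for c, v in smoothed.items()}
            assert count_hrd_loh(smoothed, genome) == brute_hrd_loh(tuples, genome)
            assert count_tai(smoothed, genome) == brute_tai(tuples, genome)
            assert count_lst(smoothed, genome) == brute_lst(tuples, genome)


class TestPlantedRecoveryAndInvariance:
    def test_planted_counts_recovered(self, genome):
        segs, truth = simulate_segments(genome, 3, 2, 4, seed=11)
        scores = score_sample(segs, genome)
        assert (scores["loh"], scores["tai"], scores["lst"]) == (3, 2, 4)
        assert scores["hrd_index"] == 9

    def test_adding_one_event_increments_by_one(self, genome):
        base = score_sample(simulate_segments(genome, 2, 2, 2, seed=5)[0], genome)
        for kind, extra in [("loh", (3, 2, 2)), ("tai", (2, 3, 2)), ("lst", (2, 2, 3))]:
            more = score_sample(simulate_segments(genome, *extra, seed=5)[0], genome)
            assert more[kind] >= 1
            assert more["hrd_index"] == sum(extra)
        assert base["hrd_index"] == 6

    def test_chromosome_order_invariance(self, genome):
        segs, _ = simulate_segments(genome, 3, 2, 4, seed=13)
        shuffled = segs.sample(frac=1.0, random_state=0)
        assert score_sample(shuffled, genome) == score_sample(segs, genome)
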