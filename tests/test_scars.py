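"""Scar engine: arm splitting, LOH/TAI/LST counting, brute-force equivalence."""

import numpy as np
import pytest

from hrdscar import (
    ScarParams,
    ValidationError,
    loh_score,
    lst_score,
    normalize_profile,
    score_profile,
    split_at_centromere,
    tai_score,
)
from hrdscar.scars import _smooth
from hrdscar.simulate import simulate_scarred_profile

from _oracles import oracle_loh, oracle_lst, oracle_tai, random_profile, smooth_fixed_points
from conftest import profile, seg

MB = 1_000_000
P = ScarParams()


def diploid_chrom(chrom="chr1", end_mb=100):
    return seg(chrom, 0, end_mb, 1, 1)


class TestSplitAtCentromere:
    def test_straddling_segment_split_into_arm_pieces(self, toy_genome):
        p = profile(seg("chr1", 40, 60, 2, 1))
        pieces = split_at_centromere(p, toy_genome)
        assert [(a.arm, a.segment.start, a.segment.end) for a in pieces] == [
            ("p", 40 * MB + 1, 45 * MB),
            ("q", 55 * MB, 60 * MB),
        ]

    def test_segment_inside_centromere_dropped(self, toy_genome):
        p = profile(seg("chr1", 46, 54, 2, 1))
        assert split_at_centromere(p, toy_genome) == ()

    def test_q_arm_segment_unchanged(self, toy_genome):
        p = profile(seg("chr1", 60, 80, 2, 1))
        (piece,) = split_at_centromere(p, toy_genome)
        assert piece.arm == "q" and piece.segment == p.segments[0]


class TestLohScore:
    def test_diploid_profile_scores_zero(self, toy_genome):
        p = profile(*[diploid_chrom(c) for c in toy_genome.chrom_names])
        assert loh_score(p, toy_genome, P)[0] == 0

    def test_interior_20mb_loh_counts(self, toy_genome):
        p = profile(seg("chr1", 0, 30, 1, 1), seg("chr1", 30, 50, 1, 0), seg("chr1", 50, 100, 1, 1))
        count, regions = loh_score(p, toy_genome, P)
        assert count == 1
        assert (regions[0].start, regions[0].end) == (30 * MB + 1, 50 * MB)

    def test_14mb_loh_below_threshold(self, toy_genome):
        p = profile(seg("chr1", 0, 30, 1, 1), seg("chr1", 30, 44, 1, 0), seg("chr1", 44, 100, 1, 1))
        assert loh_score(p, toy_genome, P)[0] == 0

    def test_whole_chromosome_loh_excluded_by_default(self, toy_genome):
        p = profile(seg("chr1", 0, 100, 1, 0))
        assert loh_score(p, toy_genome, P)[0] == 0
        relaxed = ScarParams(exclude_whole_chromosome_loh=False)
        assert loh_score(p, toy_genome, relaxed)[0] == 1

    def test_run_spans_gaps_and_centromere(self, toy_genome):
        # two (1,0) segments with an internal gap: one region, span start->end
        p = profile(seg("chr1", 0, 30, 1, 1), seg("chr1", 30, 40, 1, 0),
                    seg("chr1", 42, 60, 1, 0), seg("chr1", 60, 100, 1, 1))
        count, regions = loh_score(p, toy_genome, P)
        assert count == 1 and regions[0].end - regions[0].start + 1 == 30 * MB

    def test_homozygous_deletion_breaks_run(self, toy_genome):
        # total_cn = 0 segments are not LOH and split the run into two short halves
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 30, 1, 0),
                    seg("chr1", 30, 32, 0, 0), seg("chr1", 32, 42, 1, 0),
                    seg("chr1", 42, 100, 1, 1))
        assert loh_score(p, toy_genome, P)[0] == 0

    def test_unnormalized_profile_rejected(self, toy_genome):
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 40, 1, 1))
        with pytest.raises(ValidationError, match="normalize"):
            loh_score(p, toy_genome, P)


class TestTaiScore:
    def test_diploid_profile_scores_zero(self, toy_genome):
        p = profile(*[diploid_chrom(c) for c in toy_genome.chrom_names])
        assert tai_score(p, toy_genome, P)[0] == 0

    def test_terminal_q_arm_imbalance_counts(self, toy_genome):
        p = profile(seg("chr1", 0, 92, 1, 1), seg("chr1", 92, 100, 2, 1))
        count, regions = tai_score(p, toy_genome, P)
        assert count == 1 and regions[0].arm == "q"

    def test_interior_imbalance_not_telomeric(self, toy_genome):
        p = profile(seg("chr1", 0, 60, 1, 1), seg("chr1", 60, 70, 2, 1), seg("chr1", 70, 100, 1, 1))
        assert tai_score(p, toy_genome, P)[0] == 0

    def test_centromere_crossing_run_rejected(self, toy_genome):
        # AI from the p telomere across the centromere into q: 0 by the no-crossing rule
        p = profile(seg("chr1", 0, 70, 2, 1), seg("chr1", 70, 100, 1, 1))
        assert tai_score(p, toy_genome, P)[0] == 0

    def test_whole_chromosome_imbalance_rejected(self, toy_genome):
        p = profile(seg("chr1", 0, 100, 2, 1))
        assert tai_score(p, toy_genome, P)[0] == 0

    def test_both_telomeres_count_separately(self, toy_genome):
        p = profile(seg("chr1", 0, 10, 2, 1), seg("chr1", 10, 90, 1, 1), seg("chr1", 90, 100, 3, 1))
        count, regions = tai_score(p, toy_genome, P)
        assert count == 2 and {r.arm for r in regions} == {"p", "q"}

    def test_min_length_filter(self, toy_genome):
        p = profile(seg("chr1", 0, 92, 1, 1), seg("chr1", 92, 100, 2, 1))
        strict = ScarParams(tai_min_len=10 * MB)
        assert tai_score(p, toy_genome, strict)[0] == 0


class TestLstScore:
    def test_uniform_chromosome_scores_zero(self, toy_genome):
        p = profile(diploid_chrom())
        assert lst_score(p, toy_genome, P)[0] == 0

    def test_abutting_large_state_change_counts(self, toy_genome):
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 40, 2, 1))
        count, regions = lst_score(p, toy_genome, P)
        assert count == 1
        assert (regions[0].start, regions[0].end) == (20 * MB, 20 * MB + 1)

    def test_small_interstitial_same_state_flanks_smoothed_away(self, toy_genome):
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 22, 3, 1), seg("chr1", 22, 42, 1, 1))
        assert lst_score(p, toy_genome, P)[0] == 0

    def test_small_interstitial_different_state_flanks_keeps_break(self, toy_genome):
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 22, 3, 1), seg("chr1", 22, 42, 2, 1))
        assert lst_score(p, toy_genome, P)[0] == 1

    def test_gap_above_3mb_blocks_break(self, toy_genome):
        p = profile(seg("chr1", 0, 20, 1, 1), seg("chr1", 24, 44, 2, 1))
        assert lst_score(p, toy_genome, P)[0] == 0

    def test_arm_straddling_junction_not_counted_per_arm(self, toy_genome):
        # state change exactly at the centromere: per-arm analysis sees no pair
        p = profile(seg("chr1", 0, 50, 1, 1), seg("chr1", 50, 100, 2, 1))
        assert lst_score(p, toy_genome, P)[0] == 0
        whole = ScarParams(lst_per_arm=False)
        assert lst_score(p, toy_genome, whole)[0] == 1

    def test_smoothing_reaches_fixed_point(self, toy_genome):
        segs = [seg("chr1", 0, 20, 1, 1), seg("chr1", 20, 21, 2, 1),
                seg("chr1", 21, 23, 1, 1), seg("chr1", 23, 40, 1, 1)]
        smoothed = _smooth(segs, P.lst_max_gap_and_smooth)
        assert _smooth(smoothed, P.lst_max_gap_and_smooth) == smoothed

    @pytest.mark.parametrize("seed", range(30))
    def test_smoothing_lands_on_an_enumerated_fixed_point(self, seed, toy_genome):
        """The smallest-first smoother's result is reachable by some deletion order."""
        rng = np.random.default_rng(seed)
        p = normalize_profile(random_profile(toy_genome, rng, max_segs=6))
        segs = tuple(p.chrom_segments("chr1"))
        fps = smooth_fixed_points(segs, P.lst_max_gap_and_smooth)
        assert _smooth(list(segs), P.lst_max_gap_and_smooth) in [list(fp) for fp in fps]
        assert lst_score(p, toy_genome, P)[0] in oracle_lst(p, toy_genome, P)


class TestScoreProfile:
    def test_diploid_genome_all_zero(self, toy_genome):
        p = profile(*[diploid_chrom(c) for c in toy_genome.chrom_names])
        s = score_profile(p, toy_genome)
        assert (s.loh, s.tai, s.lst, s.hrd_sum) == (0, 0, 0, 0)

    def test_planted_counts_recovered(self, grch38):
        p, truth = simulate_scarred_profile(grch38, 3, 2, 4, seed=0)
        s = score_profile(p, grch38)
        assert (s.loh, s.tai, s.lst, s.hrd_sum) == (3, 2, 4, 9)

    def test_sum_identity_and_region_audit(self, grch38):
        p, _ = simulate_scarred_profile(grch38, 2, 3, 1, seed=5)
        s = score_profile(p, grch38)
        assert s.hrd_sum == s.loh + s.tai + s.lst
        kinds = [r.kind for r in s.regions]
        assert kinds.count("LOH") == s.loh
        assert kinds.count("TAI") == s.tai
        assert kinds.count("LST-breakpoint") == s.lst

    def test_invariant_to_stored_row_order(self, grch38, tmp_path):
        from hrdscar import read_segment_table, write_segment_table
        import pandas as pd

        p, _ = simulate_scarred_profile(grch38, 2, 2, 2, seed=9)
        f = tmp_path / "segs.tsv"
        write_segment_table([p], f)
        df = pd.read_csv(f, sep="\t")
        df.iloc[::-1].to_csv(f, sep="\t", index=False)  # reverse row order
        (back,) = read_segment_table(f, grch38)
        assert score_profile(back, grch38) == score_profile(p, grch38)

    def test_adding_disjoint_loh_increases_loh_by_one(self, grch38):
        """Monotonicity: one extra clean 17 Mb LOH block adds exactly 1 to LOH."""
        from dataclasses import replace

        p, _ = simulate_scarred_profile(grch38, 1, 1, 1, seed=2)
        base = score_profile(p, grch38)
        # carve bg | 4Mb gap | 17Mb (1,0) | 4Mb gap | bg out of a large diploid segment
        segs = list(p.segments)
        idx, target = next(
            (i, s) for i, s in enumerate(segs)
            if s.state == (1, 1) and s.span > 60 * MB
            and s.end <= grch38[s.chrom].centromere_start  # wholly in the p arm
        )
        from hrdscar.genome import Segment

        mid = target.start + 20 * MB
        segs[idx : idx + 1] = [
            replace(target, end=mid - 1),
            Segment(chrom=target.chrom, start=mid + 4 * MB, end=mid + 21 * MB,
                    total_cn=1, major_cn=1, minor_cn=0),
            replace(target, start=mid + 25 * MB),
        ]
        p2 = replace(p, segments=tuple(segs))
        s2 = score_profile(p2, grch38)
        assert s2.loh == base.loh + 1
        assert s2.tai == base.tai and s2.lst == base.lst


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_all_three_scores_match_brute_force(self, seed, toy_genome):
        rng = np.random.default_rng(1000 + seed)
        p = normalize_profile(random_profile(toy_genome, rng))
        assert loh_score(p, toy_genome, P)[0] == oracle_loh(p, toy_genome, P)
        assert tai_score(p, toy_genome, P)[0] == oracle_tai(p, toy_genome, P)
        assert lst_score(p, toy_genome, P)[0] in oracle_lst(p, toy_genome, P)
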