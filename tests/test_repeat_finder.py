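import numpy as np
import pytest

from gapcast.genome_io import GenomeSet, MatchRecord, Replicon, reverse_complement
from gapcast.repeat_finder import (
    ClassThresholds,
    RepeatFilter,
    chain_matches,
    classify,
    find_exact_maximal_repeats,
    matches_to_profile,
    merge_intervals,
    profile_genome,
)
from gapcast.synthetic_data import GenomeSpec, PlantedRepeat, make_genome

from conftest import matches_as_tuples, oracle_mems, random_dna


class TestExactDetector:
    def test_no_repeats_empty(self, rng):
        genome = GenomeSet([Replicon("r", random_dna(rng, 3000), circular=False)])
        assert find_exact_maximal_repeats(genome, 200) == []

    def test_planted_forward_copy(self, rng):
        spec = GenomeSpec(
            replicons=[(20_000, True)],
            planted_repeats=[PlantedRepeat(length=6000, copies=2, placements=[(0, 100), (0, 10_000)])],
            seed=1,
        )
        genome, _ = make_genome(spec)
        matches = find_exact_maximal_repeats(genome, 500)
        assert len(matches) == 1
        (m,) = matches
        assert m.orientation == "forward"
        # chance extension into the background adds at most a few bases
        assert 6000 <= m.len_a <= 6020

    def test_planted_inverted_copy(self):
        spec = GenomeSpec(
            replicons=[(20_000, True)],
            planted_repeats=[
                PlantedRepeat(length=600, copies=2, orientations=["F", "R"])
            ],
            seed=5,
        )
        genome, _ = make_genome(spec)
        matches = find_exact_maximal_repeats(genome, 500)
        assert len(matches) == 1
        assert matches[0].orientation == "inverted"
        assert matches[0].ref_b_start > matches[0].ref_b_end

    def test_inter_replicon_match(self, rng):
        shared = random_dna(rng, 800)
        a = random_dna(rng, 2000) + shared + random_dna(rng, 2000)
        b = random_dna(rng, 1000) + shared + random_dna(rng, 1000)
        genome = GenomeSet(
            [Replicon("chr", a, circular=False), Replicon("plas", b, circular=False)]
        )
        matches = find_exact_maximal_repeats(genome, 500)
        cross = [m for m in matches if m.replicon_a != m.replicon_b]
        assert len(cross) == 1
        assert cross[0].len_a == 800

    def test_origin_spanning_repeat_found_on_circle(self, rng):
        # one copy crosses the origin: invisible to a linear scan, found by
        # the seam-aware detector
        unit = random_dna(rng, 500)
        background = random_dna(rng, 8000)
        seq = unit[300:] + background + unit + random_dna(rng, 1000) + unit[:300]
        genome_circ = GenomeSet([Replicon("r", seq, circular=True)])
        genome_lin = GenomeSet([Replicon("r", seq, circular=False)])
        found_circ = find_exact_maximal_repeats(genome_circ, 450)
        found_lin = find_exact_maximal_repeats(genome_lin, 450)
        assert max((m.len_a for m in found_circ), default=0) >= 500
        assert max((m.len_a for m in found_lin), default=0) < 500

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_equivalence_random_genomes(self, seed):
        """Suffix-array detector equals brute-force seed-and-extend."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2000, 5000))
        seq = list(random_dna(rng, n))
        # plant a few exact repeats, one inverted
        unit1 = random_dna(rng, 400)
        unit2 = random_dna(rng, 250)
        seq[100:500] = unit1
        seq[1200:1600] = unit1
        seq[700:950] = unit2
        seq[1700:1950] = reverse_complement(unit2)
        seq = "".join(seq)
        genome = GenomeSet([Replicon("r", seq, circular=False)])
        min_len = 200
        got = matches_as_tuples(find_exact_maximal_repeats(genome, min_len))
        expected = oracle_mems(seq, min_len)
        assert got == expected

    def test_invariance_under_revcomp_and_order(self, rng):
        spec = GenomeSpec(
            replicons=[(15_000, True), (5_000, True)],
            planted_repeats=[
                PlantedRepeat(length=800, copies=2, placements=[(0, 1000), (1, 2000)])
            ],
            seed=9,
        )
        genome, _ = make_genome(spec)
        prof = profile_genome(genome)
        # reverse-complement the whole genome
        rc_genome = GenomeSet(
            [Replicon(r.name, reverse_complement(r.sequence), r.circular) for r in genome]
        )
        # permute replicon order
        perm = GenomeSet(list(genome)[::-1])
        assert profile_genome(rc_genome).max_repeat == prof.max_repeat
        assert profile_genome(perm).max_repeat == prof.max_repeat

    def test_n_runs_never_form_repeats(self, rng):
        # two 600 bp runs of N would be a perfect repeat pair if Ns matched
        seq = random_dna(rng, 1000) + "N" * 600 + random_dna(rng, 1000) + "N" * 600
        genome = GenomeSet([Replicon("r", seq, circular=False)])
        matches = find_exact_maximal_repeats(genome, 500)
        assert matches == []


class TestChaining:
    def _match(self, a0, b0, length, identity=100.0, orientation="forward"):
        if orientation == "forward":
            return MatchRecord(a0 + 1, a0 + length, b0 + 1, b0 + length,
                               identity, "r", "r", "forward")
        return MatchRecord(a0 + 1, a0 + length, b0 + length, b0 + 1,
                           identity, "r", "r", "inverted")

    def test_two_matches_small_gap_chained(self):
        # 400 bp + 400 bp with a 20 bp gap on both copies -> one 820 bp chain
        m1 = self._match(0, 5000, 400)
        m2 = self._match(420, 5420, 400)
        out = chain_matches([m1, m2], RepeatFilter(min_len=500, min_identity=0.95))
        assert len(out) == 1
        assert out[0].len_a == 820
        assert out[0].identity == pytest.approx(100 * 800 / 820, abs=1e-3)

    def test_single_match_unchanged(self):
        m = self._match(0, 5000, 600)
        out = chain_matches([m], RepeatFilter())
        assert len(out) == 1
        assert out[0].identity == 100.0
        assert out[0].len_a == 600

    def test_low_identity_chain_rejected(self):
        # 400 + 400 with 200 bp gaps: identity 0.80 < 0.95, pieces < 500 bp
        m1 = self._match(0, 5000, 400)
        m2 = self._match(600, 5600, 400)
        out = chain_matches([m1, m2], RepeatFilter(min_len=500, min_identity=0.95))
        assert out == []

    def test_inverted_chain_coordinates(self):
        # inverted: as a advances, b runs backwards
        m1 = self._match(0, 5420, 400, orientation="inverted")   # b: 5820..5421
        m2 = self._match(420, 5000, 400, orientation="inverted")  # b: 5400..5001
        out = chain_matches([m1, m2], RepeatFilter(min_len=500, min_identity=0.95))
        assert len(out) == 1
        assert out[0].orientation == "inverted"
        assert out[0].span == 820

    def test_diverged_planted_repeat_recovered_end_to_end(self):
        spec = GenomeSpec(
            replicons=[(30_000, True)],
            planted_repeats=[PlantedRepeat(length=2000, copies=2, identity=0.98)],
            seed=12,
        )
        genome, truth = make_genome(spec)
        prof = profile_genome(genome, RepeatFilter(min_len=500, min_identity=0.95))
        assert prof.repeat_count >= 2
        # every planted copy is covered >= 95% by reported intervals
        for copy in truth.repeat_copies:
            covered = 0
            for iv in prof.merged_intervals:
                covered += max(
                    0, min(iv.end, copy["end"]) - max(iv.start, copy["start"])
                )
            assert covered >= 0.95 * (copy["end"] - copy["start"])


class TestProfile:
    def test_empty_profile(self, rng):
        genome = GenomeSet([Replicon("r", random_dna(rng, 5000), circular=False)])
        prof = profile_genome(genome)
        assert prof.repeat_count == 0
        assert prof.max_repeat == 0
        assert prof.genome_class == "I"
        assert prof.merged_intervals == []

    def test_two_copy_repeat_profile(self):
        spec = GenomeSpec(
            replicons=[(50_000, True)],
            planted_repeats=[PlantedRepeat(length=6000, copies=2)],
            seed=3,
        )
        genome, _ = make_genome(spec)
        prof = profile_genome(genome)
        assert prof.repeat_count == 2
        assert 6000 <= prof.max_repeat <= 6020
        assert prof.genome_class == "I"

    def test_containment_removal(self):
        # hand-built matches: a 2 kb interval and one nested inside it
        genome = GenomeSet([Replicon("r", "A" * 10_000, circular=False)])
        outer = MatchRecord(1, 2000, 5001, 7000, 100.0, "r", "r")
        inner = MatchRecord(101, 700, 5101, 5700, 100.0, "r", "r")
        prof = matches_to_profile([outer, inner], genome, RepeatFilter(min_len=500))
        starts = sorted((iv.start, iv.end) for iv in prof.intervals)
        assert starts == [(0, 2000), (5000, 7000)]

    def test_unknown_replicon_errors(self):
        genome = GenomeSet([Replicon("r", "ACGT" * 500, circular=False)])
        bad = MatchRecord(1, 600, 1001, 1600, 100.0, "nope", "nope")
        with pytest.raises(ValueError, match="nope"):
            matches_to_profile([bad], genome)

    def test_merged_conserves_covered_bases(self):
        spec = GenomeSpec(
            replicons=[(40_000, True)],
            planted_repeats=[
                PlantedRepeat(length=1000, copies=2, placements=[(0, 1000), (0, 2001)]),
                PlantedRepeat(length=700, copies=3,
                              placements=[(0, 10_000), (0, 20_000), (0, 30_000)]),
            ],
            seed=4,
        )
        genome, _ = make_genome(spec)
        prof = profile_genome(genome)
        union = set()
        for iv in prof.intervals:
            union.update(range(iv.start, iv.end))
        merged_cover = sum(iv.length for iv in prof.merged_intervals)
        assert merged_cover == len(union)
        # merged intervals pairwise disjoint and non-abutting
        ivs = sorted(prof.merged_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            assert a.end < b.start


class TestClassify:
    @pytest.mark.parametrize(
        "count,max_rep,expected",
        [
            (0, 0, "I"),
            (3, 6000, "I"),
            (150, 6500, "II"),
            (100, 7000, "I"),    # strict boundaries: not over either threshold
            (101, 7000, "II"),
            (5, 7001, "III"),
            (500, 50_000, "III"),
        ],
    )
    def test_rules(self, count, max_rep, expected):
        assert classify(count, max_rep, ClassThresholds()) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify(-1, 0)

    def test_planted_class_iii(self):
        spec = GenomeSpec(
            replicons=[(40_000, True)],
            planted_repeats=[PlantedRepeat(length=8000, copies=2)],
            seed=6,
        )
        genome, _ = make_genome(spec)
        assert profile_genome(genome).genome_class == "III"


def test_merge_intervals_abutting():
    from gapcast.repeat_finder import RepeatInterval

    ivs = [
        RepeatInterval("r", 0, 100),
        RepeatInterval("r", 100, 200),  # abuts: merges
        RepeatInterval("r", 300, 400),
    ]
    merged = merge_intervals(ivs)
    assert [(iv.start, iv.end) for iv in merged] == [(0, 200), (300, 400)]
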