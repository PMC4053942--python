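import math

import numpy as np
import pytest
from scipy import stats

from gapcast.closure_sim import (
    SimulationConfig,
    SimulatedReadSet,
    count_unspanned,
    coverage_sweep,
    predict_closure,
    simulate_reads,
    spanning_probability,
)
from gapcast.genome_io import GenomeSet, Replicon
from gapcast.length_models import ReadLengthModel, chemistry_preset
from gapcast.repeat_finder import RepeatInterval, RepeatProfile, profile_genome
from gapcast.synthetic_data import GenomeSpec, PlantedRepeat, make_genome


def constant_model(length: int) -> ReadLengthModel:
    return ReadLengthModel(
        kind="lognormal", mu=math.log(length), sigma=0.0, max_len=length,
        name=f"const{length}",
    )


def dummy_replicon(length: int, circular: bool = True) -> Replicon:
    return Replicon("r", "A" * length, circular=circular)


class TestSimulateReads:
    def test_exact_read_count_constant_lengths(self):
        reads = simulate_reads(dummy_replicon(10_000), constant_model(1000),
                               coverage=1.0, seed=0)
        assert len(reads) == 10

    def test_stopping_rule_band(self):
        model = chemistry_preset("C2")
        rep = dummy_replicon(100_000)
        reads = simulate_reads(rep, model, coverage=20.0, seed=1)
        total = reads.total_bases
        assert 20.0 * rep.length <= total < 20.0 * rep.length + model.max_len

    def test_reproducible(self):
        model = chemistry_preset("C2")
        a = simulate_reads(dummy_replicon(50_000), model, 10.0, seed=5)
        b = simulate_reads(dummy_replicon(50_000), model, 10.0, seed=5)
        assert np.array_equal(a.starts, b.starts)
        assert np.array_equal(a.lengths, b.lengths)

    def test_uniform_starts_chisquare(self):
        reads = simulate_reads(dummy_replicon(10_000), constant_model(100),
                               coverage=1000.0, seed=2)
        assert len(reads) == 100_000
        counts, _ = np.histogram(reads.starts, bins=20, range=(0, 10_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_linear_truncation_at_end(self):
        reads = simulate_reads(dummy_replicon(5000, circular=False),
                               constant_model(2000), coverage=5.0, seed=3)
        assert np.all(reads.starts + reads.lengths <= 5000)

    def test_circular_wrap_flagged(self):
        reads = simulate_reads(dummy_replicon(5000), constant_model(2000),
                               coverage=5.0, seed=3)
        wraps = reads.wraps
        assert np.array_equal(wraps, reads.starts + reads.lengths > 5000)
        assert wraps.any()

    def test_read_longer_than_replicon_capped(self):
        reads = simulate_reads(dummy_replicon(1000), constant_model(5000),
                               coverage=2.0, seed=4)
        assert np.all(reads.lengths == 1000)


class TestCountUnspanned:
    def test_no_intervals(self):
        reads = simulate_reads(dummy_replicon(10_000), constant_model(1000), 5.0, 0)
        assert count_unspanned([], reads) == 0

    def test_reads_too_short_never_span(self):
        iv = [RepeatInterval("r", 1000, 7000)]  # 6 kb repeat
        reads = simulate_reads(dummy_replicon(50_000), constant_model(5000), 200.0, 0)
        assert count_unspanned(iv, reads, anchor=40) == 1

    def test_exact_boundary_spanning(self):
        # read length exactly R + 2*anchor: only one admissible start
        G, R, anchor = 10_000, 3000, 40
        iv = [RepeatInterval("r", 1000, 1000 + R)]
        need_start = 1000 - anchor
        reads = SimulatedReadSet(
            replicon="r", replicon_length=G, circular=True,
            starts=np.array([need_start]), lengths=np.array([R + 2 * anchor]),
        )
        assert count_unspanned(iv, reads, anchor) == 0
        reads.starts[0] += 1  # one base late: misses the left anchor
        assert count_unspanned(iv, reads, anchor) == 1

    def test_wraparound_spanning(self):
        # repeat at the origin, read starting near the end of the circle
        G = 10_000
        iv = [RepeatInterval("r", 9900, 9990)]
        reads = SimulatedReadSet(
            replicon="r", replicon_length=G, circular=True,
            starts=np.array([9700]), lengths=np.array([600]),
        )
        assert count_unspanned(iv, reads, anchor=40) == 0

    def test_whole_circle_read_spans_everything(self):
        iv = [RepeatInterval("r", 0, 9000)]  # repeat + flanks wrap the circle
        reads = SimulatedReadSet(
            replicon="r", replicon_length=10_000, circular=True,
            starts=np.array([5]), lengths=np.array([10_000]),
        )
        assert count_unspanned(iv, reads, anchor=600) == 0


class TestSpanningProbability:
    def test_never_resolved(self):
        assert spanning_probability(10_000, 3000, 2000, 100) == 1.0

    def test_single_favourable_start(self):
        G, N = 10_000, 25
        p = spanning_probability(G, 3000, 3000 + 80, N, anchor=40)
        assert p == pytest.approx((1 - 1 / G) ** N)

    def test_worked_example_vs_enumeration(self):
        G, R, L, anchor, N = 10_000, 3000, 4000, 40, 25
        # exhaustive: count start positions from which one read spans
        iv = [RepeatInterval("r", 1000, 1000 + R)]
        favourable = 0
        for start in range(G):
            reads = SimulatedReadSet(
                replicon="r", replicon_length=G, circular=True,
                starts=np.array([start]), lengths=np.array([L]),
            )
            favourable += count_unspanned(iv, reads, anchor) == 0
        p1 = 1 - favourable / G
        assert spanning_probability(G, R, L, 1, anchor) == pytest.approx(p1)
        assert spanning_probability(G, R, L, N, anchor) == pytest.approx(
            0.0893, abs=0.0005
        )

    def test_infeasible_geometry(self):
        with pytest.raises(ValueError):
            spanning_probability(1000, 990, 995, 10, anchor=40)

    def test_simulation_agrees_within_3_binomial_se(self):
        G, R, L, anchor, cov = 10_000, 3000, 4000, 40, 10.0
        N = int(math.ceil(cov * G / L))  # 25 reads per replicate
        expected = spanning_probability(G, R, L, N, anchor)
        iv = [RepeatInterval("r", 2000, 2000 + R)]
        rep = dummy_replicon(G)
        model = constant_model(L)
        trials = 800
        unresolved = 0
        for t in range(trials):
            reads = simulate_reads(rep, model, cov, seed=t)
            assert len(reads) == N
            unresolved += count_unspanned(iv, reads, anchor) > 0
        se = math.sqrt(expected * (1 - expected) / trials)
        assert abs(unresolved / trials - expected) <= 3 * se


class TestPredictClosure:
    def _repeat_genome(self, seed=3):
        spec = GenomeSpec(
            replicons=[(50_000, True)],
            planted_repeats=[PlantedRepeat(length=6000, copies=2)],
            seed=seed,
        )
        genome, _ = make_genome(spec)
        return genome, profile_genome(genome)

    def test_empty_profile_always_closed(self, rng):
        from conftest import random_dna

        genome = GenomeSet(
            [
                Replicon("chr", random_dna(rng, 20_000), circular=True),
                Replicon("plas", random_dna(rng, 4_000), circular=True),
            ]
        )
        profile = profile_genome(genome)
        cfg = SimulationConfig(coverage=20, replicates=3, seed=1)
        res = predict_closure(genome, profile, chemistry_preset("C2"), cfg)
        assert res.closed_fraction == 1.0
        assert all(r.contigs == 2 for r in res.per_replicate)

    def test_high_coverage_c2_closes_6kb_repeat(self):
        genome, profile = self._repeat_genome()
        cfg = SimulationConfig(coverage=200, replicates=5, seed=2)
        res = predict_closure(genome, profile, chemistry_preset("C2"), cfg)
        assert res.closed_fraction == 1.0
        assert res.mean_gaps == 0.0

    def test_determinism(self):
        genome, profile = self._repeat_genome()
        cfg = SimulationConfig(coverage=50, replicates=4, seed=9)
        r1 = predict_closure(genome, profile, chemistry_preset("C2"), cfg)
        r2 = predict_closure(genome, profile, chemistry_preset("C2"), cfg)
        assert [o.gaps_per_replicon for o in r1.per_replicate] == [
            o.gaps_per_replicon for o in r2.per_replicate
        ]

    def test_gap_accounting_consistency(self):
        genome, profile = self._repeat_genome()
        cfg = SimulationConfig(coverage=30, replicates=6, seed=11)
        res = predict_closure(genome, profile, chemistry_preset("C1"), cfg)
        for out in res.per_replicate:
            assert out.total_gaps == sum(out.gaps_per_replicon.values())
            assert out.contigs == sum(out.contigs_per_replicon.values())
            assert out.closed == (out.total_gaps == 0)


class TestCoverageSweep:
    def _sweep(self, models, coverages, replicates=5, seed=5):
        spec = GenomeSpec(
            replicons=[(50_000, True)],
            planted_repeats=[PlantedRepeat(length=4000, copies=2)],
            seed=7,
        )
        genome, _ = make_genome(spec)
        profile = profile_genome(genome)
        cfg = SimulationConfig(coverage=max(coverages), replicates=replicates, seed=seed)
        return coverage_sweep(genome, profile, models, coverages, cfg)

    def test_monotone_in_coverage_common_random_numbers(self):
        table = self._sweep([chemistry_preset("C2")], [10, 25, 50, 100, 200])
        closed = table.sort_values("coverage")["closed_fraction"].to_numpy()
        gaps = table.sort_values("coverage")["mean_gaps"].to_numpy()
        assert np.all(np.diff(closed) >= 0)
        assert np.all(np.diff(gaps) <= 0)

    def test_longer_chemistry_not_worse(self):
        table = self._sweep(
            [chemistry_preset("C2"), chemistry_preset("ZL")], [25, 50], replicates=20
        )
        for cov in (25, 50):
            sub = table[table.coverage == cov].set_index("model")
            assert sub.loc["ZL", "mean_gaps"] <= sub.loc["C2", "mean_gaps"]

    def test_zero_repeat_genome_all_closed(self, rng):
        from conftest import random_dna

        genome = GenomeSet([Replicon("r", random_dna(rng, 30_000), circular=True)])
        profile = profile_genome(genome)
        cfg = SimulationConfig(coverage=50, replicates=3, seed=1)
        table = coverage_sweep(genome, profile, [chemistry_preset("C2")], [10, 50], cfg)
        assert (table.closed_fraction == 1.0).all()

    def test_scaling_lengths_up_never_adds_gaps(self):
        spec = GenomeSpec(
            replicons=[(50_000, True)],
            planted_repeats=[PlantedRepeat(length=5000, copies=2)],
            seed=13,
        )
        genome, _ = make_genome(spec)
        profile = profile_genome(genome)
        rep = genome.replicons[0]
        for seed in range(10):
            reads = simulate_reads(rep, chemistry_preset("C2"), 20.0, seed=seed)
            gaps = count_unspanned(profile.merged_intervals, reads)
            scaled = SimulatedReadSet(
                replicon=reads.replicon,
                replicon_length=reads.replicon_length,
                circular=reads.circular,
                starts=reads.starts,
                lengths=np.minimum(reads.lengths * 2, rep.length),
            )
            assert count_unspanned(profile.merged_intervals, scaled) <= gaps
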