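import math
from dataclasses import replace

import numpy as np
import pytest

from rwmapkit.intervals import GenomicInterval, IntervalSet
from rwmapkit.mapping import GenotypeCall, Marker, TestOutcome, map_mutation
from rwmapkit.simulate import (
    SimConfig,
    default_deletion_panel,
    default_markers,
    derive_deletion_outcomes,
    simulate_f2_cohort,
    simulate_gamete,
    simulate_intercross_weaned,
    simulate_screen,
    simulate_variant_tables,
    write_screen,
)
from rwmapkit.variants import filter_candidates


def haldane_r(d_morgans: float) -> float:
    return (1 - math.exp(-2 * d_morgans)) / 2


class TestSimulateGamete:
    LOCI = np.array([10.0, 500_000.0, 999_990.0])
    H = (np.zeros(3, dtype=np.int8), np.ones(3, dtype=np.int8))

    def test_zero_genetic_length_gives_parental_haplotype(self, rng):
        for _ in range(200):
            g = simulate_gamete(self.H, self.LOCI, 1_000_000, 0.0, rng)
            assert g.min() == g.max()  # unrecombined

    def test_single_locus_segregates_half_half(self, rng):
        loci = np.array([500.0])
        hits = sum(
            int(simulate_gamete((np.array([0]), np.array([1])), loci, 1000,
                                0.05, rng)[0])
            for _ in range(50_000)
        )
        assert hits / 50_000 == pytest.approx(0.5, abs=0.01)

    @pytest.mark.parametrize("d", [0.05, 0.20])
    def test_recombinant_fraction_matches_haldane(self, rng, d):
        """Two loci d Morgans apart recombine at (1−e^(−2d))/2."""
        region = 1_000_000
        genetic_length = 0.5  # Morgans over the whole region
        sep = d / genetic_length * region
        loci = np.array([region / 2 - sep / 2, region / 2 + sep / 2])
        h = (np.zeros(2, dtype=np.int8), np.ones(2, dtype=np.int8))
        n = 50_000
        rec = sum(
            int(g[0] != g[1])
            for g in (simulate_gamete(h, loci, region, genetic_length, rng)
                      for _ in range(n))
        )
        assert rec / n == pytest.approx(haldane_r(d), abs=0.01)

    def test_negative_length_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_gamete(self.H, self.LOCI, 1_000_000, -1.0, rng)


class TestSimulateF2Cohort:
    def test_fixed_seed_is_bit_identical(self):
        cfg = SimConfig(seed=11, n_f2=40)
        assert simulate_f2_cohort(cfg) == simulate_f2_cohort(cfg)

    def test_different_seed_differs(self):
        a = simulate_f2_cohort(SimConfig(seed=1, n_f2=40))
        b = simulate_f2_cohort(SimConfig(seed=2, n_f2=40))
        assert a != b

    def test_no_live_animal_b6b6_at_marker_on_mutation(self):
        """With a marker placed exactly at the mutation, live-animal
        frequencies follow the conditional Mendelian ratios (0 B6/B6,
        2/3 het, 1/3 Cast/Cast)."""
        markers = (Marker(33_250_000, "mMut"),)
        cfg = SimConfig(seed=5, n_f2=2000, markers=markers)
        table = simulate_f2_cohort(cfg)
        calls = [a.calls[0] for a in table.animals]
        n = len(calls)
        freq = {c: calls.count(c) / n for c in set(calls)}
        assert freq.get(GenotypeCall.B6B6, 0) == 0
        assert freq[GenotypeCall.HET] == pytest.approx(2 / 3, abs=0.03)
        assert freq[GenotypeCall.CASTCAST] == pytest.approx(1 / 3, abs=0.03)
        # lethality removes ~1/4 of conceptuses
        assert n / cfg.n_f2 == pytest.approx(0.75, abs=0.03)

    def test_far_marker_approaches_unlinked_quarter(self):
        """A marker far from the mutation at high recombination rate is
        effectively unlinked: B6/B6 appears in ~1/4 of live animals."""
        markers = (Marker(60_000_000, "mFar"),)
        cfg = SimConfig(seed=7, n_f2=2000, markers=markers,
                        true_mutation_pos=1_000_000, cM_per_Mb=10.0)
        table = simulate_f2_cohort(cfg)
        calls = [a.calls[0] for a in table.animals]
        b6b6 = calls.count(GenotypeCall.B6B6) / len(calls)
        assert b6b6 == pytest.approx(0.25, abs=0.03)

    def test_genotype_noise_knobs(self):
        cfg = SimConfig(seed=3, n_f2=200, missing_rate=0.2)
        table = simulate_f2_cohort(cfg)
        calls = [c for a in table.animals for c in a.calls]
        miss = sum(c is GenotypeCall.MISSING for c in calls) / len(calls)
        assert miss == pytest.approx(0.2, abs=0.03)


class TestDeriveDeletionOutcomes:
    def test_mutation_inside_min_extent_always_fails(self, rng):
        from rwmapkit.mapping import Deletion

        d = Deletion("dfX", GenomicInterval("5", 1_000_000, 2_000_000),
                     GenomicInterval("5", 900_000, 2_100_000))
        cfg = SimConfig(true_mutation_pos=1_500_000, deletions=(d,), seed=0)
        for _ in range(200):
            tests, segs = derive_deletion_outcomes(cfg, rng)
            assert tests[0].outcome is TestOutcome.FAILS
            seg = segs["dfX"]
            assert 900_000 <= seg.start <= 1_000_000
            assert 2_000_000 <= seg.end <= 2_100_000

    def test_mutation_outside_max_extent_always_complements(self, rng):
        from rwmapkit.mapping import Deletion

        d = Deletion("dfX", GenomicInterval("5", 1_000_000, 2_000_000),
                     GenomicInterval("5", 900_000, 2_100_000))
        cfg = SimConfig(true_mutation_pos=5_000_000, deletions=(d,), seed=0)
        for _ in range(200):
            tests, _ = derive_deletion_outcomes(cfg, rng)
            assert tests[0].outcome is TestOutcome.COMPLEMENTS

    def test_uncertainty_zone_mass_matches_geometry(self, rng):
        """A mutation centred in the left breakpoint-uncertainty zone fails
        at the uniform-probability mass of breakpoints proximal to it."""
        from rwmapkit.mapping import Deletion

        d = Deletion("dfX", GenomicInterval("5", 1_000_000, 2_000_000),
                     GenomicInterval("5", 900_000, 2_100_000))
        # mutation 30% of the way into [900k, 1000k): fails iff left
        # breakpoint lands proximal to it: p = 0.3 (+ half-open edge effects)
        cfg = SimConfig(true_mutation_pos=930_001, deletions=(d,), seed=0)
        fails = sum(
            derive_deletion_outcomes(cfg, rng)[0][0].outcome is TestOutcome.FAILS
            for _ in range(10_000)
        )
        assert fails / 10_000 == pytest.approx(0.3, abs=0.02)


class TestIntercrossWeaned:
    def test_noncomplementing_cross_weans_no_transheterozygotes(self, rng):
        for n in (0, 1, 17, 100):
            counts = simulate_intercross_weaned(n, complementing=False, rng=rng)
            assert counts.weaned_non_balancer == 0
            assert counts.born_total == n
            assert counts.weaned_balancer + (counts.died_pre_wean or 0) == n

    def test_complementing_cross_weans_a_third(self, rng):
        counts = simulate_intercross_weaned(30_000, complementing=True, rng=rng)
        assert counts.died_pre_wean == 0
        frac = counts.weaned_non_balancer / counts.born_total
        assert frac == pytest.approx(1 / 3, abs=0.01)

    def test_zero_born(self, rng):
        counts = simulate_intercross_weaned(0, complementing=True, rng=rng)
        assert counts.total_weaned == 0


class TestSimulateVariantTables:
    def test_zero_noise_leaves_only_planted_variant(self):
        cfg = SimConfig(seed=9, variant_noise=(0, 0, 0))
        tables, known = simulate_variant_tables(cfg)
        assert len(tables["mutant"]) == 1
        [v] = tables["mutant"]
        assert v.pos == cfg.true_mutation_pos
        assert len(known) == 0

    def test_noise_counts_and_sharing_structure(self):
        cfg = SimConfig(seed=9, variant_noise=(5, 7, 3))
        tables, known = simulate_variant_tables(cfg)
        assert len(tables["mutant"]) == 1 + 5 + 7 + 3
        assert len(tables["control_strain"]) == 5 + 7
        assert len(tables["control_b6"]) == 7
        assert len(known) == 3

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(seed=12)
        a, _ = simulate_variant_tables(cfg)
        b, _ = simulate_variant_tables(cfg)
        assert a == b


class TestEndToEnd:
    def test_screen_is_pure_function_of_config(self):
        cfg = SimConfig(seed=21, n_f2=30)
        a, b = simulate_screen(cfg), simulate_screen(cfg)
        assert a.genotype_table == b.genotype_table
        assert a.deletion_tests == b.deletion_tests
        assert a.variant_tables == b.variant_tables

    def test_mapping_contains_truth_and_filter_recovers_variant(self):
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_f2=50)
            s = simulate_screen(cfg)
            initial = IntervalSet([GenomicInterval(cfg.chrom, 0, cfg.region_length)])
            catalog = {d.name: d for d in cfg.deletion_list}
            cr = map_mutation(initial, s.deletion_tests, catalog,
                              s.genotype_table, cfg.mutation_id)
            assert cr.region.contains_1based(s.truth.mutation_pos)
            res = filter_candidates(
                s.variant_tables["mutant"],
                [s.variant_tables["control_strain"],
                 s.variant_tables["control_b6"]],
                cr.region, s.known_variants,
            )
            assert [v.pos for v in res.retained] == [s.truth.mutation_pos]

    def test_write_screen_round_trips_through_file_readers(self, tmp_path):
        from rwmapkit.mapping import (read_deletion_tests, read_deletions,
                                      read_genotype_table)
        from rwmapkit.variants import read_variant_tsv, read_vcf

        cfg = SimConfig(seed=4, n_f2=20, variant_noise=(2, 2, 2))
        s = simulate_screen(cfg)
        write_screen(s, tmp_path)
        table = read_genotype_table(tmp_path / "genotypes.tsv",
                                    tmp_path / "markers.tsv")
        assert table == s.genotype_table
        assert read_deletion_tests(tmp_path / "deletion_tests.tsv") == s.deletion_tests
        dels = read_deletions(tmp_path / "deletions.tsv")
        assert dels == {d.name: d for d in cfg.deletion_list}
        assert read_variant_tsv(tmp_path / "variants_mutant.tsv") == \
            s.variant_tables["mutant"]
        assert read_vcf(tmp_path / "variants_mutant.vcf") == \
            s.variant_tables["mutant"]
        assert SimConfig.from_yaml(tmp_path / "sim_config.yaml") == cfg


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimConfig(true_mutation_pos=0)
        with pytest.raises(ValueError):
            SimConfig(cM_per_Mb=0)
        with pytest.raises(ValueError):
            SimConfig(n_f2=0)

    def test_defaults_are_well_formed(self):
        cfg = SimConfig()
        markers = cfg.marker_list
        assert markers == sorted(markers)
        assert all(1 <= m.position <= cfg.region_length for m in markers)
        for d in cfg.deletion_list:
            assert d.max_extent.start <= d.min_extent.start
            assert d.min_extent.end <= d.max_extent.end
        assert cfg.genetic_length_morgans == pytest.approx(0.3045)
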