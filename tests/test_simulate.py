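import numpy as np
import pandas as pd
import pytest

from poolhaf.io_formats import ChromosomeTable
from poolhaf.simulate import (
    CrossingScheme,
    PoolReadModel,
    SimGenome,
    build_mlw,
    default_genome,
    field_population_scheme,
    recovery_experiment,
    sample_pool,
    simulate_pool_reads,
    simulate_population,
)


@pytest.fixture(scope="module")
def small_genome():
    return default_genome(np.random.default_rng(99), n_chromosomes=3,
                          chrom_length_bp=10_000_000, markers_per_chrom=150)


class TestSimulatePopulation:
    def test_f1_is_fully_heterozygous(self, small_genome):
        pop = simulate_population(small_genome, CrossingScheme(0, 0), 20, 1)
        assert np.all(pop.heterozygote_fractions() == 1.0)
        assert np.all(pop.donor_frequencies() == 0.5)

    def test_mean_donor_frequency_halves_per_backcross(self, small_genome):
        # expectation (1/2)^(n_bc + 1), unaffected by selfing
        n = 6000
        for n_bc in (0, 1, 2):
            pop = simulate_population(small_genome, CrossingScheme(n_bc, 1),
                                      n, 10 + n_bc)
            dosage = pop.dosage_matrix() / 2.0
            mean = dosage.mean()
            se = dosage.mean(axis=1).std() / np.sqrt(n)
            assert mean == pytest.approx(0.5 ** (n_bc + 1), abs=3 * se)

    def test_heterozygosity_halves_per_selfing(self, small_genome):
        n = 6000
        hets = []
        for n_self in (0, 1, 2):
            pop = simulate_population(small_genome, CrossingScheme(2, n_self),
                                      n, 42)
            hets.append(pop.heterozygote_fractions().mean())
        assert hets[0] == pytest.approx(0.25, abs=0.01)
        assert hets[1] / hets[0] == pytest.approx(0.5, rel=0.1)
        assert hets[2] / hets[1] == pytest.approx(0.5, rel=0.1)

    def test_family_structure_induces_between_locus_drift(self, small_genome):
        # descent from 24 BC2 founders spreads true locus frequencies far
        # beyond the iid-lineage case while preserving the 12.5% mean
        n = 4000
        iid = simulate_population(small_genome, CrossingScheme(2, 2), n, 7)
        fam = simulate_population(small_genome, field_population_scheme(),
                                  n, 7)
        # genome-wide drift from 24 founder lineages: ~3 sigma band
        assert fam.donor_frequencies().mean() == pytest.approx(0.125, abs=0.09)
        assert fam.donor_frequencies().std() > 2 * iid.donor_frequencies().std()

    def test_same_seed_is_bit_identical(self, small_genome):
        a = simulate_population(small_genome, CrossingScheme(2, 2), 200, 5)
        b = simulate_population(small_genome, CrossingScheme(2, 2), 200, 5)
        assert np.array_equal(a.dosage_matrix(), b.dosage_matrix())

    def test_empty_marker_grid_rejected(self):
        with pytest.raises(ValueError):
            SimGenome((), pd.DataFrame(columns=["marker_id", "chrom",
                                                "pos_bp", "pos_cM"]))


class TestSamplePool:
    def test_full_pool_equals_population_truth(self, small_genome):
        pop = simulate_population(small_genome, CrossingScheme(2, 2), 500, 3)
        sub, truth = sample_pool(pop, 500, 1)
        assert np.array_equal(truth, pop.donor_frequencies())

    def test_fixed_seed_reproduces_subsample(self, small_genome):
        pop = simulate_population(small_genome, CrossingScheme(2, 2), 500, 3)
        _, t1 = sample_pool(pop, 300, 11)
        _, t2 = sample_pool(pop, 300, 11)
        assert np.array_equal(t1, t2)

    def test_oversized_pool_rejected(self, small_genome):
        pop = simulate_population(small_genome, CrossingScheme(2, 2), 50, 3)
        with pytest.raises(ValueError):
            sample_pool(pop, 51, 1)

    def test_subsample_within_hypergeometric_error(self, small_genome):
        pop = simulate_population(small_genome, CrossingScheme(2, 2), 6000, 8)
        n_pool = 300
        sub, truth = sample_pool(pop, n_pool, 9)
        pop_freq = pop.donor_frequencies()
        dos = pop.dosage_matrix() / 2.0
        sd = dos.std(axis=0)
        fpc = np.sqrt((pop.n_individuals - n_pool) / (pop.n_individuals - 1))
        se = np.maximum(sd / np.sqrt(n_pool) * fpc, 1e-12)
        within = np.abs(truth - pop_freq) <= 3 * se
        assert within.mean() >= 0.95


class TestSimulatePoolReads:
    def _loci(self, n, truth):
        return pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, n + 1),
                             "truth": truth})

    def test_fixed_truth_zero_and_one(self):
        model = PoolReadModel(mean_depth=8)
        sites0 = simulate_pool_reads(self._loci(200, 0.0), model, 1)
        assert all(s.alt_reads == 0 for s in sites0)
        sites1 = simulate_pool_reads(self._loci(200, 1.0), model, 1)
        assert all(s.ref_reads == 0 for s in sites1)

    def test_moments_match_binomial_poisson_oracle(self):
        n, p, depth_mean = 10_000, 0.125, 10.0
        model = PoolReadModel(mean_depth=depth_mean)
        sites = simulate_pool_reads(self._loci(n, p), model, 12)
        covered = [s for s in sites if s.total_reads > 0]
        est = np.array([s.alt_reads / s.total_reads for s in covered])
        se = est.std() / np.sqrt(len(est))
        assert est.mean() == pytest.approx(p, abs=3 * se)
        # E[(p_hat - p)^2] = p(1-p) * E[1/d | d>=1]
        inv_d = np.mean([1 / s.total_reads for s in covered])
        expected_mse = p * (1 - p) * inv_d
        mse = np.mean((est - p) ** 2)
        assert mse == pytest.approx(expected_mse, rel=0.1)

    def test_qual_is_deterministic_in_depth(self):
        model = PoolReadModel(fixed_depth=4)
        sites = simulate_pool_reads(self._loci(10, 0.5), model, 3)
        assert all(s.qual == 60.0 for s in sites)


class TestBuildMlw:
    def _genome(self, marker_pos, length=None, spacing=1500):
        if length is None:
            # keep terminal flanks below the 1 Mb window cap
            length = marker_pos[-1] + 100_000
        rows = [(f"m{i}", "chr1", p, p * 150.0 / length)
                for i, p in enumerate(marker_pos)]
        markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp",
                                              "pos_cM"])
        from poolhaf.simulate import SimChromosome
        return SimGenome((SimChromosome("chr1", length, 150.0),), markers,
                         pseudo_snp_spacing=spacing)

    def test_flank_extension_replays_extension_rule(self):
        genome = self._genome([100_000, 102_000])
        wins, loci = build_mlw(genome.markers, genome)
        gap = 2000
        ext = int(np.floor(0.45 * gap))
        assert wins[0].end == 100_000 + ext
        assert wins[1].start == 102_000 - ext
        # every pseudo-SNP lies on the grid inside exactly one window
        for row in loci.itertuples(index=False):
            if row.is_pseudo:
                assert row.pos % genome.pseudo_snp_spacing == 0
                inside = [w for w in wins if w.start <= row.pos <= w.end]
                assert len(inside) == 1
                assert inside[0].anchor_id == row.anchor_id

    def test_small_window_dropped(self):
        # middle marker's window spans 1 + 2*floor(0.45*500) = 451 < 500 bp
        genome = self._genome([100_000, 100_500, 101_000])
        wins, loci = build_mlw(genome.markers, genome)
        assert [w.anchor_id for w in wins] == ["m0", "m2"]
        assert "m1" not in set(loci["anchor_id"])

    def test_uniform_mb_grid_all_retained_nonoverlapping(self):
        pos = list(range(1_000_000, 30_000_001, 1_000_000))
        genome = self._genome(pos, length=31_000_000)
        wins, _ = build_mlw(genome.markers, genome)
        assert len(wins) == len(pos)
        for a, b in zip(wins, wins[1:]):
            assert a.end < b.start

    def test_anchor_marker_included_as_non_pseudo_locus(self):
        genome = self._genome([100_000, 200_000])
        _, loci = build_mlw(genome.markers, genome)
        anchors = loci[~loci["is_pseudo"]]
        assert sorted(anchors["pos"]) == [100_000, 200_000]


class TestRecoveryExperiment:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny():
        return default_genome(np.random.default_rng(4), n_chromosomes=2,
                              chrom_length_bp=3_000_000,
                              markers_per_chrom=40)

    def test_deep_sequencing_of_full_pool_removes_all_error(self, tiny):
        # pool == population and near-infinite depth: the only noise source
        # left is binomial sampling at depth 10,000 per SNP
        table = recovery_experiment(
            genome=tiny, scheme=field_population_scheme(), n_pool=400,
            model=PoolReadModel(fixed_depth=10_000),
            coverage_thresholds=(0,), seed=6, n_population=400)
        haf = table[table.level == "haf"].iloc[0]
        snp = table[table.level == "snp"].iloc[0]
        assert haf.pearson_r > 0.999 and haf.rmse < 0.005
        assert snp.pearson_r > 0.99 and snp.rmse < 0.01

    def test_same_seed_reproduces_table(self, tiny):
        kwargs = dict(genome=tiny, n_pool=100, n_population=1000, seed=13,
                      coverage_thresholds=(0, 50))
        a = recovery_experiment(**kwargs)
        b = recovery_experiment(**kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_aggregation_beats_single_snp_estimates(self, tiny):
        table = recovery_experiment(genome=tiny, n_pool=300,
                                    n_population=2400, seed=3,
                                    coverage_thresholds=(0,))
        snp = table[table.level == "snp"].iloc[0]
        haf = table[table.level == "haf"].iloc[0]
        assert haf.rmse < snp.rmse
        assert haf.pearson_r > snp.pearson_r
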