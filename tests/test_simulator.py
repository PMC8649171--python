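import numpy as np
import pytest

from cinscape.genome_model import Region, hg38_layout, toy_layout
from cinscape.mifish import bundled_panel
from cinscape.presets import FNE1_FOUNDER, simulate_preset
from cinscape.scoring import consensus_profile
from cinscape.simulate import (
    CinParameters,
    CountModel,
    ExtinctionError,
    FounderKaryotype,
    SimulationError,
    apply_missegregation,
    apply_segmental,
    apply_wgd,
    gate_by_dna_content,
    simulate_dna_content,
    simulate_mifish,
    simulate_population,
    simulate_read_counts,
)


class TestFounder:
    def test_zero_rates_preserve_founder(self, toy):
        founder = FounderKaryotype(base_ploidy=2)
        params = CinParameters(generations=5, carrying_capacity=40,
                               sample_size=10, seed=1)
        pop = simulate_population(founder, params, toy)
        assert (pop.matrix == 2).all()

    def test_fne1_founder_monosomies(self):
        """Near-diploid founder: state 1 exactly over 9p, chr15 and chrX."""
        layout = hg38_layout()
        pop = simulate_preset("fne1", seed=3, sample_size=10)
        consensus = consensus_profile(pop)
        expected = np.full(layout.n_bins, 2, dtype=int)
        from cinscape.genome_model import region_to_bins

        for region, delta in FNE1_FOUNDER.aberrations:
            bins = region_to_bins(layout, region)
            expected[bins.start:bins.stop] += delta
        assert (consensus == expected).all()

    def test_negative_founder_rejected(self, toy):
        founder = FounderKaryotype(
            base_ploidy=1, aberrations=((Region("chrA", 0, 1_000_000), -2),)
        )
        with pytest.raises(Exception):
            founder.build(toy)


class TestElementaryEvents:
    def test_missegregation_disomic_parent(self, toy):
        parent = np.full(toy.n_bins, 2, dtype=np.int16)
        a, b = apply_missegregation(parent, toy, chrom_index=0)
        assert (a[:10] == 3).all() and (b[:10] == 1).all()
        assert (a[10:] == 2).all() and (b[10:] == 2).all()

    def test_missegregation_monosomic_parent_reaches_nullisomy(self, toy):
        parent = np.full(toy.n_bins, 1, dtype=np.int16)
        a, b = apply_missegregation(parent, toy, chrom_index=1)
        assert (a[10:] == 2).all() and (b[10:] == 0).all()

    def test_missegregation_nullisomic_chromosome_rejected(self, toy):
        parent = np.zeros(toy.n_bins, dtype=np.int16)
        with pytest.raises(SimulationError):
            apply_missegregation(parent, toy, chrom_index=0)

    def test_missegregation_conservation(self, toy, rng):
        """Reciprocal events: per-bin daughter sums equal twice the parent."""
        for _ in range(200):
            parent = rng.integers(1, 5, size=toy.n_bins).astype(np.int16)
            ci = int(rng.integers(2))
            a, b = apply_missegregation(parent, toy, ci,
                                        direction=int(rng.integers(2)) * 2 - 1)
            assert (a + b == 2 * parent).all()

    def test_segmental_conservation_and_extent(self, toy, rng):
        for _ in range(200):
            parent = rng.integers(1, 5, size=toy.n_bins).astype(np.int16)
            k = int(rng.integers(1, 10))
            a, b = apply_segmental(parent, toy, 0, k)
            assert (a + b == 2 * parent).all()
            assert (a[:k] == parent[:k]).all()
            assert (a[k:10] == parent[k:10] + 1).all()

    def test_wgd_doubles_everything(self):
        profile = np.array([2, 2, 1, 3], dtype=np.int16)
        assert (apply_wgd(profile) == [4, 4, 2, 6]).all()
        # monosomy becomes disomy on the tetraploid background
        assert apply_wgd(profile)[2] == 2
        assert (apply_wgd(apply_wgd(np.full(5, 2))) == 8).all()


class TestPopulationProcess:
    def test_seed_determinism(self, toy):
        founder = FounderKaryotype(base_ploidy=2)
        params = CinParameters(p_mis=0.02, p_seg=0.02, generations=8,
                               carrying_capacity=60, sample_size=20, seed=42)
        a = simulate_population(founder, params, toy)
        b = simulate_population(founder, params, toy)
        assert (a.matrix == b.matrix).all()

    def test_extinction_is_reported(self, toy):
        founder = FounderKaryotype(base_ploidy=2)
        # WGD every division with a cap of 3 kills every daughter immediately
        params = CinParameters(p_wgd=1.0, max_copy=3, generations=2,
                               carrying_capacity=10, sample_size=5, seed=0)
        with pytest.raises(ExtinctionError):
            simulate_population(founder, params, toy)

    def test_deviation_fraction_matches_lineage_oracle(self, toy):
        """Population deviation frequency agrees with an independent
        single-lineage Monte-Carlo that re-draws per-chromosome Bernoulli
        mis-segregations along one daughter's history."""
        p_mis, generations = 0.01, 10
        founder = FounderKaryotype(base_ploidy=2)
        founder_profile = founder.build(toy)

        n_reps, sample = 150, 40
        fractions = []
        for rep in range(n_reps):
            params = CinParameters(p_mis=p_mis, generations=generations,
                                   carrying_capacity=80, sample_size=sample,
                                   seed=1000 + rep)
            pop = simulate_population(founder, params, toy)
            fractions.append(
                float((pop.matrix != founder_profile).any(axis=1).mean())
            )
        fractions = np.asarray(fractions)

        oracle_rng = np.random.default_rng(99)
        n_lineages = 20_000
        deviated = 0
        alive = 0
        for _ in range(n_lineages):
            delta = np.zeros(2, dtype=int)  # net copy change per chromosome
            dead = False
            for _ in range(generations):
                for ci in range(2):
                    if oracle_rng.random() < p_mis and 2 + delta[ci] >= 1:
                        delta[ci] += 1 if oracle_rng.random() < 0.5 else -1
                if (2 + delta < 1).any():  # nullisomy is lethal
                    dead = True
                    break
            if not dead:
                alive += 1
                deviated += int((delta != 0).any())
        oracle = deviated / alive

        se = np.sqrt(fractions.var(ddof=1) / n_reps
                     + oracle * (1 - oracle) / alive)
        assert abs(fractions.mean() - oracle) < 3 * se


class TestReadCounts:
    def test_poisson_mean(self, toy, rng):
        """Flat diploid, variance = mean: sample mean within 3 s.e. of 2d*gc."""
        model = CountModel(mean_reads_per_copy_per_bin=30.0, dispersion=1.0)
        profile = np.full(toy.n_bins, 2, dtype=np.int16)
        draws = np.concatenate(
            [simulate_read_counts(profile, model, rng) for _ in range(200)]
        )
        mu = 60.0
        se = np.sqrt(mu / len(draws))
        assert abs(draws.mean() - mu) < 3 * se

    def test_overdispersed_variance_inflation(self, toy, rng):
        model = CountModel(mean_reads_per_copy_per_bin=50.0, dispersion=3.0)
        profile = np.full(toy.n_bins, 2, dtype=np.int16)
        draws = np.concatenate(
            [simulate_read_counts(profile, model, rng) for _ in range(500)]
        )
        # variance should be near dispersion * mean, far from Poisson
        assert draws.var() / draws.mean() > 2.0

    def test_nullisomic_bin_yields_zero(self, toy, rng):
        profile = np.zeros(toy.n_bins, dtype=np.int16)
        counts = simulate_read_counts(profile, CountModel(), rng)
        assert (counts == 0).all()

    def test_doubling_profile_doubles_mean(self, toy):
        model = CountModel(mean_reads_per_copy_per_bin=40.0, dispersion=2.0)
        profile = np.full(toy.n_bins, 2, dtype=np.int16)
        means = []
        for prof in (profile, apply_wgd(profile)):
            rng = np.random.default_rng(7)  # paired seeds
            draws = np.concatenate(
                [simulate_read_counts(prof, model, rng) for _ in range(500)]
            )
            means.append(draws.mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.02)

    def test_gc_bias_shifts_means(self, toy, rng):
        gc = np.linspace(0.5, 1.5, toy.n_bins)
        model = CountModel(mean_reads_per_copy_per_bin=50.0, dispersion=1.0,
                           gc_factor=gc)
        profile = np.full(toy.n_bins, 2, dtype=np.int16)
        draws = np.stack(
            [simulate_read_counts(profile, model, rng) for _ in range(400)]
        )
        ratio = draws.mean(axis=0) / (100.0 * gc)
        assert np.abs(ratio - 1).max() < 0.1


class TestMiFishSimulation:
    def test_error_free_founder_pattern(self):
        """Stable founder: single CDKN2A signal, two copies at other gene loci."""
        layout = hg38_layout()
        panel = bundled_panel()
        profile = FNE1_FOUNDER.build(layout)
        cell = simulate_mifish(profile, panel, layout, error_rate=0.0)
        assert cell.counts["CDKN2A"] == 1
        for probe, count in cell.counts.items():
            if probe != "CDKN2A":
                assert count == 2

    def test_error_free_tetraploid_all_fours(self, toy):
        panel = bundled_panel()
        layout = hg38_layout()
        profile = np.full(layout.n_bins, 4, dtype=np.int16)
        cell = simulate_mifish(profile, panel, layout, error_rate=0.0)
        assert set(cell.counts.values()) == {4}

    def test_error_rate_matches_binomial_oracle(self, rng):
        layout = hg38_layout()
        panel = bundled_panel()
        profile = np.full(layout.n_bins, 2, dtype=np.int16)
        error_rate, n_cells = 0.05, 2000
        deviations = 0
        for i in range(n_cells):
            cell = simulate_mifish(profile, panel, layout, error_rate, rng,
                                   cell_id=f"c{i}")
            deviations += sum(v != 2 for v in cell.counts.values())
        n_draws = n_cells * panel.n_probes
        se = np.sqrt(error_rate * (1 - error_rate) / n_draws)
        assert abs(deviations / n_draws - error_rate) < 3 * se


class TestDnaContent:
    def test_flat_diploid_noise_free(self, toy):
        from cinscape.profiles import PopulationMatrix

        pop = PopulationMatrix(layout=toy,
                               matrix=np.full((20, toy.n_bins), 2, np.int16))
        values = simulate_dna_content(pop, cv=0.0, g2_fraction=0.0)
        assert (values == 1.0).all()

    def test_flat_tetraploid_noise_free(self, toy):
        from cinscape.profiles import PopulationMatrix

        pop = PopulationMatrix(layout=toy,
                               matrix=np.full((20, toy.n_bins), 4, np.int16))
        assert (simulate_dna_content(pop, cv=0.0) == 2.0).all()

    def test_g2_fraction_creates_8c_shoulder(self, toy, rng):
        from cinscape.profiles import PopulationMatrix

        pop = PopulationMatrix(layout=toy,
                               matrix=np.full((2000, toy.n_bins), 4, np.int16))
        values = simulate_dna_content(pop, cv=0.0, g2_fraction=0.3, rng=rng)
        frac_8c = (values == 4.0).mean()
        assert abs(frac_8c - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 2000)

    def test_sort_gate_selects_ploidy(self, toy):
        from cinscape.profiles import PopulationMatrix

        matrix = np.vstack(
            [np.full((10, toy.n_bins), 2), np.full((5, toy.n_bins), 4)]
        ).astype(np.int16)
        pop = PopulationMatrix(layout=toy, matrix=matrix)
        assert gate_by_dna_content(pop, "2c").n_cells == 10
        assert gate_by_dna_content(pop, "4c").n_cells == 5
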