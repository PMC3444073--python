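"""Genetic operators, evolution loop, size sweep, repeats, band grouping."""
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from gasam import ga, sam, spectra
from gasam.ga import (
    Chromosome,
    GAConfig,
    evolve,
    fitness,
    group_bands,
    init_population,
    mutate,
    repeat_runs,
    roulette_select,
    single_point_crossover,
    sweep_chromosome_size,
)


def _grid(n=12, lo=3.0, hi=5.2, mask=None):
    m = np.ones(n, bool) if mask is None else np.asarray(mask)
    return spectra.SpectralGrid(np.linspace(lo, hi, n), m)


class _FixedCut:
    """Generator stub that returns a fixed crossover cut position."""

    def __init__(self, cut, rng_seed=0):
        self._cut = cut
        self._rng = np.random.default_rng(rng_seed)

    def integers(self, lo, hi=None):
        return self._cut

    def choice(self, *args, **kwargs):
        return self._rng.choice(*args, **kwargs)


class TestChromosome:
    def test_sorted_and_distinct(self):
        assert Chromosome((5, 1, 3)).genes == (1, 3, 5)
        with pytest.raises(ValueError, match="duplicate"):
            Chromosome((1, 1, 2))


class TestInitPopulation:
    def test_exactly_k_valid_bands_forces_unique_solution(self):
        grid = _grid(6, mask=[True, False, True, False, True, False])
        cfg = GAConfig(k=3, population_size=20, seed=0)
        pop = init_population(cfg, grid)
        assert all(ch.genes == (0, 2, 4) for ch in pop)

    def test_seed_determinism(self):
        grid = _grid()
        cfg = GAConfig(k=4, population_size=50, seed=7)
        assert init_population(cfg, grid) == init_population(cfg, grid)

    def test_k_exceeding_valid_bands_errors(self):
        with pytest.raises(ValueError, match="valid bands"):
            init_population(GAConfig(k=13, population_size=10), _grid(12))

    def test_single_gene_draws_uniform(self):
        grid = _grid(4)
        cfg = GAConfig(k=1, population_size=10_000, seed=1)
        pop = init_population(cfg, grid)
        counts = np.bincount([ch.genes[0] for ch in pop], minlength=4)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestFitness:
    def test_planted_bands_reach_perfection_on_low_noise(self, tiny_split):
        feature_bands = sorted(
            tiny_split.train.grid.nearest_band(c) for c in (3.2, 4.0, 4.8)
        )
        assert fitness(Chromosome(tuple(feature_bands)), tiny_split) >= 85.0

    def test_flat_bands_near_chance(self, paperlike_split):
        """Species differ only at planted features, so far-off bands give
        roughly 1-in-13 accuracy."""
        grid = paperlike_split.train.grid
        flat = Chromosome(tuple(grid.nearest_band(w) for w in (4.5, 5.0, 8.6, 12.5, 13.5)))
        acc = fitness(flat, paperlike_split)
        assert acc <= 100 * 2 / 13 + 5.0

    def test_deterministic(self, tiny_split):
        ch = Chromosome((1, 5, 9))
        assert fitness(ch, tiny_split) == fitness(ch, tiny_split)


class TestRoulette:
    def test_single_positive_fitness_always_selected(self):
        pop = [Chromosome((0,)), Chromosome((1,)), Chromosome((2,))]
        rng = np.random.default_rng(0)
        parents = roulette_select(pop, [100.0, 0.0, 0.0], 50, rng)
        assert all(p.genes == (0,) for p in parents)

    def test_equal_fitness_is_uniform(self):
        pop = [Chromosome((i,)) for i in range(4)]
        rng = np.random.default_rng(1)
        parents = roulette_select(pop, [10.0] * 4, 10_000, rng)
        counts = np.bincount([p.genes[0] for p in parents], minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_proportional_selection_rate(self):
        pop = [Chromosome((0,)), Chromosome((1,))]
        rng = np.random.default_rng(2)
        n = 10_000
        parents = roulette_select(pop, [75.0, 25.0], n, rng)
        n_first = sum(p.genes == (0,) for p in parents)
        lo, hi = stats.binom.interval(0.99, n, 0.75)
        assert lo <= n_first <= hi

    def test_all_zero_falls_back_to_uniform(self, caplog):
        pop = [Chromosome((i,)) for i in range(3)]
        rng = np.random.default_rng(3)
        parents = roulette_select(pop, [0.0, 0.0, 0.0], 300, rng)
        assert len({p.genes for p in parents}) == 3

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            roulette_select([Chromosome((0,))], [-1.0], 1, np.random.default_rng(0))


class TestCrossover:
    def test_disjoint_parents_mechanical_splice(self):
        a = Chromosome((1, 2, 3, 4, 5))
        b = Chromosome((10, 20, 30, 40, 50))
        valid = np.arange(60)
        ca, cb = single_point_crossover(a, b, valid, _FixedCut(2))
        assert set(ca.genes) == {1, 2, 30, 40, 50}
        assert set(cb.genes) == {10, 20, 3, 4, 5}

    @pytest.mark.parametrize("cut", [1, 2, 3, 4])
    def test_identical_parents_reproduce_themselves(self, cut):
        a = Chromosome((2, 4, 6, 8, 10))
        ca, cb = single_point_crossover(a, a, np.arange(12), _FixedCut(cut))
        assert ca.genes == a.genes and cb.genes == a.genes

    def test_duplicate_repair_draws_fresh_band(self):
        # splice puts 9 into the child twice; repair must draw a fresh band
        a = Chromosome((1, 9, 11))
        b = Chromosome((2, 3, 9))
        valid = np.arange(12)
        ca, _ = single_point_crossover(a, b, valid, _FixedCut(2))
        assert len(set(ca.genes)) == 3
        assert {1, 9} <= set(ca.genes)

    def test_children_always_valid(self):
        rng = np.random.default_rng(4)
        valid = np.arange(20)
        for _ in range(200):
            a = Chromosome(tuple(rng.choice(valid, 5, replace=False)))
            b = Chromosome(tuple(rng.choice(valid, 5, replace=False)))
            for child in single_point_crossover(a, b, valid, rng):
                assert len(set(child.genes)) == 5
                assert child.genes == tuple(sorted(child.genes))

    def test_k1_is_a_copy(self):
        a, b = Chromosome((3,)), Chromosome((7,))
        assert single_point_crossover(a, b, np.arange(10), _FixedCut(1)) == (a, b)


class TestMutate:
    def test_pm_zero_is_identity(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        ch = Chromosome((1, 5, 9))
        for _ in range(100):
            assert mutate(ch, 0.0, grid, rng) == ch

    def test_pm_one_with_two_bands_forces_swap(self):
        grid = _grid(2, lo=3.0, hi=4.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert mutate(Chromosome((0,)), 1.0, grid, rng).genes == (1,)

    def test_mutation_rate_matches_pm(self):
        grid = _grid()
        rng = np.random.default_rng(5)
        ch = Chromosome((1, 5, 9))
        n = 30_000
        pm = 0.01
        mutated = sum(mutate(ch, pm, grid, rng) != ch for _ in range(n))
        lo, hi = stats.binom.interval(0.99, n, pm)
        assert lo <= mutated <= hi


class TestEvolve:
    def test_single_feasible_chromosome_converges_immediately(self, tiny_split):
        grid = tiny_split.train.grid
        mask = np.zeros(12, bool)
        mask[[2, 6, 9]] = True
        constrained = spectra.SpectralGrid(grid.wavelengths_um, mask)
        lib = spectra.SpectralLibrary(
            constrained, tiny_split.train.values,
            tiny_split.train.species_codes, tiny_split.train.leaf_ids,
        )
        vlib = spectra.SpectralLibrary(
            constrained, tiny_split.validation.values,
            tiny_split.validation.species_codes, tiny_split.validation.leaf_ids,
        )
        split = spectra.SplitLibrary(lib, vlib, seed=0)
        cfg = GAConfig(k=3, population_size=10, max_generations=5,
                       plateau_generations=2, seed=0)
        res = evolve(split, cfg)
        assert res.winner.genes == (2, 6, 9)
        assert res.best_fitness_by_generation[0] == res.winner_fitness

    def test_seed_reproducibility(self, tiny_split):
        cfg = GAConfig(k=3, population_size=40, max_generations=15,
                       plateau_generations=5, seed=21)
        a, b = evolve(tiny_split, cfg), evolve(tiny_split, cfg)
        assert a.winner == b.winner
        np.testing.assert_array_equal(
            a.best_fitness_by_generation, b.best_fitness_by_generation
        )
        np.testing.assert_array_equal(
            a.gene_frequency_by_generation, b.gene_frequency_by_generation
        )

    def test_elitism_makes_best_fitness_monotone(self, tiny_split):
        cfg = GAConfig(k=3, population_size=60, max_generations=25,
                       plateau_generations=10, seed=3)
        res = evolve(tiny_split, cfg)
        assert np.all(np.diff(res.best_fitness_by_generation) >= 0)
        assert res.winner_fitness == res.best_fitness_by_generation[-1]

    def test_gene_frequency_conserves_population(self, tiny_split):
        cfg = GAConfig(k=3, population_size=30, max_generations=10,
                       plateau_generations=4, seed=8)
        res = evolve(tiny_split, cfg)
        totals = res.gene_frequency_by_generation.sum(axis=1)
        np.testing.assert_array_equal(totals, 30 * 3)

    def test_matches_exhaustive_optimum_on_small_instance(self, tiny_split):
        ev = sam.BatchSAM(tiny_split)
        best = max(ev.accuracy(c) for c in combinations(range(12), 3))
        for seed in range(3):
            cfg = GAConfig(k=3, population_size=300, max_generations=40,
                           plateau_generations=15, seed=seed)
            assert evolve(tiny_split, cfg).winner_fitness == best


class TestSweep:
    def test_zero_threshold_takes_smallest_k(self, tiny_split):
        cfg = GAConfig(k=1, population_size=30, max_generations=8,
                       plateau_generations=3, fitness_threshold=0.0, seed=0)
        sweep = sweep_chromosome_size(tiny_split, cfg, [1, 2, 3])
        assert sweep.minimal_k == 1

    def test_unreachable_threshold_reports_none(self, tiny_split):
        cfg = GAConfig(k=1, population_size=30, max_generations=8,
                       plateau_generations=3, fitness_threshold=101.0, seed=0)
        sweep = sweep_chromosome_size(tiny_split, cfg, [1, 2])
        assert sweep.minimal_k is None


class TestRepeatRuns:
    def test_single_run_reduces_to_evolve(self, tiny_library):
        cfg = GAConfig(k=3, population_size=30, max_generations=10,
                       plateau_generations=4, seed=5)
        rep = repeat_runs(tiny_library, cfg, n_runs=1, n_train=3)
        split = spectra.split_per_species(tiny_library, 3, rep.split_seeds[0])
        import dataclasses

        direct = evolve(split, dataclasses.replace(cfg, seed=rep.runs[0].seed))
        assert rep.runs[0].winner == direct.winner
        assert rep.runs[0].winner_fitness == direct.winner_fitness

    def test_pooled_histogram_conserves_genes(self, tiny_library):
        cfg = GAConfig(k=3, population_size=30, max_generations=10,
                       plateau_generations=4, seed=5)
        rep = repeat_runs(tiny_library, cfg, n_runs=4, n_train=3)
        assert rep.pooled_gene_counts.sum() == 4 * 3
        assert rep.pooled_wavelengths.size == 4 * 3


class TestGroupBands:
    def test_single_location_single_group(self):
        groups = group_bands([3.5, 3.5, 3.5], gap_um=0.1)
        assert len(groups) == 1
        assert groups[0].sd_um == 0.0
        assert groups[0].n_genes == 3

    def test_two_clusters_with_known_means(self):
        groups = group_bands([3.40, 3.44, 3.48, 9.74, 9.87, 10.00], gap_um=0.5)
        assert len(groups) == 2
        assert groups[0].mean_um == pytest.approx(3.44, abs=1e-12)
        assert groups[1].mean_um == pytest.approx(9.87, abs=1e-12)
        assert groups[0].region == "mid infrared"
        assert groups[1].region == "thermal infrared"

    @pytest.mark.parametrize("seed", [0, 1])
    def test_shrinking_gap_never_merges_groups(self, seed):
        rng = np.random.default_rng(seed)
        wl = rng.uniform(2.5, 14.0, 40)
        counts = [len(group_bands(wl, g)) for g in (1.0, 0.5, 0.25, 0.1)]
        assert counts == sorted(counts)

    def test_group_stats_are_consistent(self):
        for g in group_bands(np.random.default_rng(3).uniform(2.5, 14, 30), 0.3):
            assert g.wl_min_um <= g.mean_um <= g.wl_max_um
            assert g.n_genes >= 1
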