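"""Genetic-algorithm seed search (CGEMGA)."""

import numpy as np
import pytest

from cgemga.cgem import build_module
from cgemga.ga import (Chromosome, GAParams, evaluate_fitness,
                       evolve_generation, initialize_population, run_cgemga,
                       size_adjusted_msr)
from cgemga.matrix import DiscretizedMatrix, discretize
from cgemga.synthetic import PlantedModuleSpec, generate, recovery_score
from conftest import naive_msr


def disc_from(states, q=None):
    states = np.asarray(states)
    q = int(states.max()) + 1 if q is None else q
    return DiscretizedMatrix(q, [np.empty(0)] * states.shape[0], states)


@pytest.fixture
def toy():
    rng = np.random.default_rng(7)
    states = rng.integers(0, 3, size=(15, 10))
    states[:6, :5] = np.tile([[0], [1], [2], [0], [1], [2]], (1, 5))
    values = states + rng.uniform(-0.2, 0.2, size=states.shape)
    return disc_from(states), values


class TestInitializePopulation:
    def test_deterministic(self, toy):
        disc, _ = toy
        params = GAParams(population_size=5, discriminating_size=4)
        a = initialize_population(disc, params, np.random.default_rng(3))
        b = initialize_population(disc, params, np.random.default_rng(3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.genotype, y.genotype)

    def test_forced_full_subset(self):
        disc = disc_from(np.zeros((2, 3), dtype=int), q=1)
        params = GAParams(population_size=4, discriminating_size=3)
        pop = initialize_population(disc, params, np.random.default_rng(0))
        for ch in pop:
            assert sorted(ch.genotype.tolist()) == [0, 1, 2]

    def test_genotypes_valid(self, toy):
        disc, _ = toy
        params = GAParams(population_size=100, discriminating_size=6)
        pop = initialize_population(disc, params, np.random.default_rng(5))
        for ch in pop:
            g = ch.genotype
            assert g.size == 6
            assert np.unique(g).size == 6
            assert g.min() >= 0 and g.max() < disc.n_samples

    def test_population_size_validation(self, toy):
        disc, _ = toy
        with pytest.raises(ValueError, match="population_size"):
            initialize_population(disc, GAParams(population_size=1),
                                  np.random.default_rng(0))


class TestEvaluateFitness:
    def test_constant_planted_block_scores_zero(self):
        states = np.zeros((5, 6), dtype=int)
        values = np.zeros((5, 6))
        ch = Chromosome([0, 1, 2])
        f = evaluate_fitness(ch, disc_from(states, q=1), values,
                             alpha=0.1, min_genes=2)
        assert f == 0.0

    def test_alpha_violation_penalized_never_admissible(self, toy):
        disc, values = toy
        ch = Chromosome([0, 1, 2, 3, 4])
        f = evaluate_fitness(ch, disc, values, alpha=1.0, min_genes=2)
        admissible = evaluate_fitness(Chromosome([0, 1, 2, 3, 4]), disc, values,
                                      alpha=0.1, min_genes=2)
        # coverage deficit pushes the score far above any admissible fitness
        assert f > admissible

    def test_empty_module_sentinel(self):
        states = np.array([[0, 1, 2]])
        ch = Chromosome([0, 1, 2])
        f = evaluate_fitness(ch, disc_from(states), np.zeros((1, 3)),
                             alpha=0.1, min_genes=1)
        assert f == np.inf

    def test_admissible_fitness_is_adjusted_msr_of_module(self, toy):
        """Cross-module consistency: fitness equals an independent MSR
        recomputation on (genes of G) × C, size-adjusted."""
        disc, values = toy
        ch = Chromosome([0, 1, 2])
        f = evaluate_fitness(ch, disc, values, alpha=0.1, min_genes=2)
        mod = build_module(disc, ch.seed(), values)
        raw = naive_msr(values, mod.genes, mod.samples)
        i, j = mod.n_genes, mod.n_samples
        assert f == pytest.approx(raw / ((1 - 1 / i) * (1 - 1 / j)), rel=1e-12)


class TestEvolveGeneration:
    def _evaluated_pop(self, disc, values, params, rng):
        pop = initialize_population(disc, params, rng)
        for ch in pop:
            evaluate_fitness(ch, disc, values, params.alpha, params.min_genes)
        return pop

    def test_no_variation_preserves_best_and_genotypes(self, toy):
        disc, values = toy
        params = GAParams(population_size=12, discriminating_size=4,
                          crossover_prob=0.0, mutation_prob=0.0, alpha=0.1,
                          min_genes=1)
        pop = self._evaluated_pop(disc, values, params, np.random.default_rng(2))
        originals = {tuple(ch.genotype.tolist()) for ch in pop}
        new = evolve_generation(pop, params, np.random.default_rng(3),
                                disc.n_samples)
        assert len(new) == len(pop)
        assert {tuple(ch.genotype.tolist()) for ch in new} <= originals
        for ch in new:
            if ch.module is None:
                evaluate_fitness(ch, disc, values, params.alpha, params.min_genes)
        assert min(ch.fitness for ch in new) == min(ch.fitness for ch in pop)

    def test_elitism_keeps_best(self, toy):
        disc, values = toy
        params = GAParams(population_size=20, discriminating_size=4, alpha=0.1,
                          min_genes=1)
        pop = self._evaluated_pop(disc, values, params, np.random.default_rng(4))
        before = min(ch.key() for ch in pop)
        new = evolve_generation(pop, params, np.random.default_rng(5),
                                disc.n_samples)
        for ch in new:
            if ch.module is None:
                evaluate_fitness(ch, disc, values, params.alpha, params.min_genes)
        assert min(ch.key() for ch in new) <= before

    def test_deterministic_offspring(self, toy):
        disc, values = toy
        params = GAParams(population_size=10, discriminating_size=4, alpha=0.1)
        pop = self._evaluated_pop(disc, values, params, np.random.default_rng(6))
        a = evolve_generation(pop, params, np.random.default_rng(7), disc.n_samples)
        b = evolve_generation(pop, params, np.random.default_rng(7), disc.n_samples)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.genotype, y.genotype)

    def test_offspring_genotypes_repaired(self, toy):
        disc, values = toy
        params = GAParams(population_size=30, discriminating_size=5,
                          mutation_prob=0.5, alpha=0.1)
        pop = self._evaluated_pop(disc, values, params, np.random.default_rng(8))
        new = evolve_generation(pop, params, np.random.default_rng(9),
                                disc.n_samples)
        for ch in new:
            assert np.unique(ch.genotype).size == ch.genotype.size
            assert ch.genotype.max() < disc.n_samples


class TestRunCgemga:
    def test_noise_free_planted_block_recovered_exactly(self):
        spec = PlantedModuleSpec(num_genes_total=80, num_samples_total=24,
                                 module_genes=12, module_samples=10,
                                 noise_sd=0.0, rng_seed=42)
        matrix, truth = generate(spec)
        disc = discretize(matrix, spec.num_states)
        params = GAParams(population_size=60, num_restarts=4,
                          discriminating_size=5, rng_seed=43)
        result = run_cgemga(disc, matrix, params)
        assert result.modules
        best = result.modules[0]
        assert best.msr == pytest.approx(0.0, abs=1e-20)
        gj, sj = recovery_score(best, truth)
        assert gj == 1.0 and sj == 1.0

    def test_traces_monotone_and_bounded(self, toy):
        disc, values = toy
        params = GAParams(population_size=20, num_restarts=3, max_generations=15,
                          discriminating_size=4, alpha=0.1, min_genes=3,
                          rng_seed=11)
        result = run_cgemga(disc, values, params)
        assert len(result.restart_traces) == 3
        for trace in result.restart_traces:
            seq = trace.best_fitness_per_generation
            assert len(seq) <= params.max_generations + 1
            assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_deterministic_end_to_end(self, toy):
        disc, values = toy
        params = GAParams(population_size=20, num_restarts=2, max_generations=10,
                          discriminating_size=4, alpha=0.1, min_genes=3,
                          rng_seed=12)
        r1 = run_cgemga(disc, values, params)
        r2 = run_cgemga(disc, values, params)
        assert r1.n_evaluations == r2.n_evaluations
        assert [m.to_record() for m in r1.modules] == [m.to_record() for m in r2.modules]
        assert (r1.trace.best_fitness_per_generation
                == r2.trace.best_fitness_per_generation)

    def test_best_not_worse_than_any_evaluated_admissible(self, toy):
        """Best-so-far tracking: the returned module's fitness is a lower
        bound over everything the restart evaluated, so re-evaluating the
        winning seed reproduces its fitness."""
        disc, values = toy
        params = GAParams(population_size=25, num_restarts=2, max_generations=10,
                          discriminating_size=4, alpha=0.1, min_genes=3,
                          rng_seed=13)
        result = run_cgemga(disc, values, params)
        assert result.modules
        best = result.modules[0]
        assert size_adjusted_msr(best) == pytest.approx(
            min(size_adjusted_msr(m) for m in result.modules))

    def test_all_restarts_discarded_warns_and_returns_empty(self):
        states = np.array([[0, 1, 2, 0, 1], [1, 2, 0, 1, 2]])
        disc = disc_from(states)
        values = np.zeros((2, 5))
        params = GAParams(population_size=6, num_restarts=2, max_generations=3,
                          discriminating_size=3, min_genes=10, rng_seed=14)
        with pytest.warns(UserWarning, match="discarded"):
            result = run_cgemga(disc, values, params)
        assert result.modules == []
        assert result.trace is None

    def test_budget_parity_with_no_variation(self, toy):
        """With crossover and mutation off, the GA degenerates to random
        multistart: its result can never be worse than the best of its own
        initial populations."""
        disc, values = toy
        params = GAParams(population_size=30, num_restarts=2, max_generations=5,
                          crossover_prob=0.0, mutation_prob=0.0,
                          discriminating_size=4, alpha=0.1, min_genes=3,
                          rng_seed=15)
        result = run_cgemga(disc, values, params)
        # replay the same initial populations independently
        seq = np.random.SeedSequence(params.rng_seed)
        init_best = np.inf
        for child in seq.spawn(params.num_restarts):
            pop = initialize_population(disc, params, np.random.default_rng(child))
            for ch in pop:
                evaluate_fitness(ch, disc, values, params.alpha, params.min_genes)
            init_best = min(init_best, min(ch.fitness for ch in pop))
        assert result.modules
        assert size_adjusted_msr(result.modules[0]) <= init_best + 1e-12
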