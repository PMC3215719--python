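"""Wright-Fisher engine: mutation, reproduction, ancestry, fixation events."""

import numpy as np
import pytest
from scipy import stats

from asexadapt import (DFEParams, ExtinctionError, FixationTimeoutError,
                       MutationRecord, build_fixture_population,
                       compact_fixed_mutations, detect_common_ancestor,
                       init_population, mutate, reproduce, run_until_fixation)
from asexadapt.engine import collect_fixation, find_mrca


class TestInit:
    def test_founding_population(self):
        pop = init_population(10_000)
        assert pop.N == 10_000
        assert pop.generation == 0
        assert np.all(pop.fitness == 1.0)
        assert all(pop.mutations_of(i) == [] for i in (0, 9_999))

    def test_minimal_population(self):
        assert init_population(2).N == 2

    @pytest.mark.parametrize("N", [0, 1])
    def test_too_small_rejected(self, N):
        with pytest.raises(ValueError):
            init_population(N)


class TestFixture:
    def test_fitness_is_effect_product(self):
        pop = build_fixture_population(
            parent_arrays=[[0, 0, 1]],
            mutations=[(1, 0, "beneficial", 0.1), (1, 0, "deleterious", 0.05)],
            N=3)
        assert pop.fitness[0] == pytest.approx(1.1 * 0.95)

    def test_lethal_mutation_zeroes_fitness(self):
        pop = build_fixture_population(
            parent_arrays=[[0, 1]],
            mutations=[(1, 1, "deleterious", 1.0)], N=2)
        assert pop.fitness[1] == 0.0

    def test_empty_mutations(self):
        pop = build_fixture_population(parent_arrays=[[0, 1], [1, 0]], N=2)
        assert np.all(pop.fitness == 1.0)

    def test_inconsistent_spec_lists_fields(self):
        with pytest.raises(ValueError, match="parent indices out of range"):
            build_fixture_population(parent_arrays=[[0, 5]], N=2)
        with pytest.raises(ValueError, match="unknown kind"):
            build_fixture_population(parent_arrays=[[0, 1]],
                                     mutations=[(0, 0, "meh", 0.1)], N=2)
        with pytest.raises(ValueError, match="generation"):
            build_fixture_population(parent_arrays=[[0, 1]],
                                     mutations=[(7, 0, "beneficial", 0.1)], N=2)


class TestMutate:
    def test_zero_rates_noop(self, dfe_default, rng):
        pop = init_population(100)
        before = pop.fitness.copy()
        mutate(pop, 0.0, 0.0, dfe_default, rng)
        np.testing.assert_array_equal(pop.fitness, before)
        assert pop.mutations_of(0) == []

    def test_negative_rate_rejected(self, dfe_default, rng):
        with pytest.raises(ValueError):
            mutate(init_population(10), -0.1, 0.0, dfe_default, rng)

    def test_total_count_poisson(self, dfe_default):
        """Total new mutations ~ Poisson(N U): within 3 sqrt(N U) of the mean."""
        rng = np.random.default_rng(8)
        pop = init_population(10_000)
        mutate(pop, 0.1, 0.1, dfe_default, rng)
        total = sum(len(b) for b in pop.mut_log[0])
        assert abs(total - 2000) < 3 * np.sqrt(2000)

    def test_fitness_matches_mutation_log(self, dfe_default):
        """w_i equals the product over the individual's mutations (Eq-3 style)."""
        rng = np.random.default_rng(9)
        pop = init_population(50)
        for _ in range(10):
            mutate(pop, 0.05, 0.2, dfe_default, rng)
            reproduce(pop, rng)
        for i in range(0, 50, 7):
            assert pop.fitness[i] == pytest.approx(
                pop.recomputed_fitness(i), rel=1e-12)


class TestReproduce:
    def test_selection_weights(self):
        """Fitness (1,0): every offspring descends from the fit parent."""
        rng = np.random.default_rng(0)
        pop = init_population(2)
        pop.fitness = np.array([1.0, 0.0])
        reproduce(pop, rng)
        assert np.all(pop.labels == 0)

    def test_extinction_raises(self):
        pop = init_population(3)
        pop.fitness = np.zeros(3)
        with pytest.raises(ExtinctionError, match="generation 0"):
            reproduce(pop, np.random.default_rng(0))

    def test_population_size_constant(self, dfe_default):
        rng = np.random.default_rng(10)
        pop = init_population(500)
        for _ in range(20):
            mutate(pop, 0.01, 0.05, dfe_default, rng)
            reproduce(pop, rng)
            assert len(pop.fitness) == 500

    def test_offspring_counts_multinomial(self):
        """Weights (2,1,1) -> parent probabilities (1/2, 1/4, 1/4)."""
        rng = np.random.default_rng(11)
        counts = np.zeros(3)
        for _ in range(2000):
            pop = init_population(3)
            pop.fitness = np.array([2.0, 1.0, 1.0])
            reproduce(pop, rng)
            counts += np.bincount(pop.labels, minlength=3)
        n = counts.sum()
        res = stats.chisquare(counts, n * np.array([0.5, 0.25, 0.25]))
        assert res.pvalue > 0.01

    def test_uniform_offspring_distribution(self):
        """Equal fitness: offspring counts are Multinomial(N, uniform)."""
        rng = np.random.default_rng(12)
        N = 1000
        counts = np.zeros(N)
        for _ in range(100):
            pop = init_population(N)
            reproduce(pop, rng)
            counts += np.bincount(pop.pedigree[0], minlength=N)
        res = stats.chisquare(counts, counts.sum() / N)
        assert res.pvalue > 0.01


def brute_force_mrca(pedigree, N):
    """Oracle: enumerate every individual's descendant set per generation."""
    T = len(pedigree)
    best = None
    for g in range(T):  # candidate ancestor generation
        n_at_g = N
        desc = [{i} for i in range(n_at_g)]
        for gg in range(g, T):
            parents = pedigree[gg]
            new = [set() for _ in range(n_at_g)]
            for child, par in enumerate(parents):
                for anc in range(n_at_g):
                    if par in desc[anc]:
                        new[anc].add(child)
            desc = new
        full = [a for a in range(n_at_g) if len(desc[a]) == N]
        if full:
            best = (g, full[0])  # most recent generation wins overall
    return best


class TestCommonAncestor:
    def test_forced_coalescence(self):
        # both gen-2 individuals descend from individual 0 at gen 1
        assert detect_common_ancestor([np.array([0, 1]), np.array([0, 0])]) \
            == (1, 0)

    def test_no_pedigree_means_distinct_founders(self):
        assert detect_common_ancestor([]) is None

    def test_no_coalescence(self):
        assert detect_common_ancestor([np.array([0, 1]), np.array([1, 0])]) \
            is None

    def test_agrees_with_descendant_set_oracle(self):
        """Random pedigrees, N <= 10, T <= 50: exact match with enumeration."""
        rng = np.random.default_rng(13)
        for _ in range(1000):
            N = int(rng.integers(2, 11))
            T = int(rng.integers(1, 51))
            ped = [rng.integers(0, N, size=N) for _ in range(T)]
            assert detect_common_ancestor(ped, N) == brute_force_mrca(ped, N)


class TestRunUntilFixation:
    def test_neutral_mutation_free_event(self):
        rec = run_until_fixation(50, 0.0, 0.0, DFEParams(20.0, 10.0),
                                 np.random.default_rng(14))
        assert rec.n_b_event == 0 and rec.n_d_event == 0
        assert rec.w_ca == 1.0
        assert rec.mrca_gen >= 0 and rec.t_fix > rec.mrca_gen

    def test_timeout(self):
        with pytest.raises(FixationTimeoutError):
            run_until_fixation(200, 0.0, 0.0, DFEParams(20.0, 10.0),
                               np.random.default_rng(15), max_generations=3)

    def test_neutral_tfix_matches_founder_fixation_oracle(self):
        """Whole-population coalescence time equals the time for one founder
        lineage to absorb; compared against an independent count-vector
        simulation of the same neutral process."""
        N, reps = 50, 400
        rng = np.random.default_rng(16)
        sim = np.array([
            run_until_fixation(N, 0.0, 0.0, DFEParams(20.0, 10.0),
                               rng).t_fix
            for _ in range(reps)])
        oracle_rng = np.random.default_rng(17)
        oracle = []
        for _ in range(reps):
            counts = np.ones(N)
            t = 0
            while counts.max() < N:
                counts = oracle_rng.multinomial(N, counts / N).astype(float)
                t += 1
            oracle.append(t)
        oracle = np.array(oracle)
        se = np.sqrt(sim.var() / reps + oracle.var() / reps)
        assert abs(sim.mean() - oracle.mean()) < 3 * se

    def test_mixed_regime_event_composition(self):
        """High-input regime: deleterious hitchhikers fix with factors > 0.99
        typically, alongside beneficial drivers."""
        rng = np.random.default_rng(18)
        recs = [run_until_fixation(1000, 2e-4, 2e-1, DFEParams(20.0, 10.0),
                                   rng) for _ in range(30)]
        nb = sum(r.n_b_event for r in recs)
        nd = sum(r.n_d_event for r in recs)
        assert nb > 0 and nd > 0
        del_effects = np.concatenate(
            [r.effects[~r.beneficial] for r in recs])
        assert np.median(del_effects) > 0.99


class TestCompaction:
    def test_folds_shared_mutations_into_background(self):
        # two founders; gen1 both descend from founder 0 who carries +0.1
        pop = build_fixture_population(
            parent_arrays=[[0, 0]],
            mutations=[(0, 0, "beneficial", 0.1)], N=2)
        assert pop.has_common_ancestor()
        compact_fixed_mutations(pop)
        assert pop.background_fitness == pytest.approx(1.1)
        assert pop.mutations_of(0) == [] and pop.mutations_of(1) == []

    def test_noop_without_common_ancestor(self):
        pop = build_fixture_population(parent_arrays=[[0, 1]], N=2)
        gen_before, anchor_before = pop.generation, pop.anchor_gen
        compact_fixed_mutations(pop)
        assert (pop.generation, pop.anchor_gen) == (gen_before, anchor_before)

    def test_absolute_fitness_preserved(self, dfe_default):
        """background x relative fitness is unchanged by compaction."""
        rng = np.random.default_rng(19)
        pop = init_population(40)
        while not pop.has_common_ancestor():
            mutate(pop, 0.02, 0.1, dfe_default, rng)
            reproduce(pop, rng)
        absolute_before = pop.background_fitness * pop.fitness
        compact_fixed_mutations(pop)
        absolute_after = pop.background_fitness * pop.fitness
        np.testing.assert_allclose(absolute_after, absolute_before, rtol=1e-12)
        # relative fitness still matches the (truncated) mutation log
        for i in range(0, 40, 11):
            assert pop.fitness[i] == pytest.approx(
                pop.recomputed_fitness(i), rel=1e-9)


class TestSelectionAccuracy:
    @pytest.mark.parametrize("s", [0.0, 0.05, 0.2])
    def test_single_mutant_fixation_probability(self, s):
        """Empirical fixation frequency of one mutant in N=20 vs the exact
        21-state multinomial-induced Markov-chain absorption probability."""
        N, trials = 20, 20_000
        # exact absorption probability from one copy
        P = np.zeros((N + 1, N + 1))
        for k in range(N + 1):
            pk = k * (1 + s) / (k * (1 + s) + (N - k))
            P[k] = stats.binom.pmf(np.arange(N + 1), N, pk)
        A = np.eye(N + 1) - P
        A[0] = 0.0
        A[0, 0] = 1.0
        A[N] = 0.0
        A[N, N] = 1.0
        b = np.zeros(N + 1)
        b[N] = 1.0
        exact = np.linalg.solve(A, b)[1]
        if s == 0.0:
            assert exact == pytest.approx(1 / N, rel=1e-9)

        rng = np.random.default_rng(100 + int(s * 100))
        fixed = 0
        for _ in range(trials):
            pop = init_population(N)
            pop.fitness[0] = 1.0 + s  # resident single mutant
            while True:
                reproduce(pop, rng)
                k = int((pop.labels == 0).sum())
                if k == 0:
                    break
                if k == N:
                    fixed += 1
                    break
        se = np.sqrt(exact * (1 - exact) / trials)
        assert abs(fixed / trials - exact) < 3 * se


def test_mean_fitness_nondecreasing_without_deleterious(dfe_default):
    """With Ud=0 the expected mean-fitness trajectory is non-decreasing:
    one-sided check on the average long-run slope over replicates."""
    slopes = []
    for r in range(50):
        rng = np.random.default_rng(3000 + r)
        pop = init_population(100)
        w0 = pop.mean_fitness()
        for _ in range(200):
            mutate(pop, 1e-3, 0.0, dfe_default, rng)
            reproduce(pop, rng)
        slopes.append(pop.mean_fitness() - w0)
    assert np.mean(slopes) > 0
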