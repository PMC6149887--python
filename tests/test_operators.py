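"""Genetic operators: history-difference mutation, elite-parent-preserving
crossover, baselines, and Solis–Wets local search."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from gadock.genome import GeneBounds, GenomeSpace, docking_space
from gadock.fixtures import make_chain_ligand
from gadock.operators import (
    HistoryArchive,
    Individual,
    cauchy_mutation,
    ce_crossover,
    ed_mutation,
    proportional_selection,
    solis_wets_search,
    two_point_crossover,
)
from gadock.scoring import ObjectiveFunction


def archive_with(best, best_fit, sub, sub_fit):
    a = HistoryArchive()
    a.observe(np.asarray(sub, dtype=float), sub_fit)
    a.observe(np.asarray(best, dtype=float), best_fit)
    return a


class TestEdMutation:
    def test_branch2_formula_direct_substitution(self):
        # m=2, M_opt=1, M_sub=3, theta=0.5, delta=0.25
        # -> 2 + 0.5*(1-3) + 0.25*(1-2) = 0.75
        bounds = GeneBounds([-1e6], [1e6])
        arch = archive_with([1.0], 0.0, [3.0], 1.0)
        out = ed_mutation(np.array([2.0]), arch, bounds, beta=0.0,
                          rng=np.random.default_rng(0),
                          theta=np.array([0.5]), delta=np.array([0.25]))
        assert out[0] == pytest.approx(0.75, abs=1e-15)

    def test_branch2_arithmetic_oracle_random_cases(self, rng):
        bounds = GeneBounds(np.full(6, -1e9), np.full(6, 1e9))
        for _ in range(1000):
            m, best, sub = rng.normal(scale=5.0, size=(3, 6))
            th, de = rng.uniform(size=(2, 6))
            arch = archive_with(best, 0.0, sub, 1.0)
            out = ed_mutation(m, arch, bounds, beta=0.0, rng=rng,
                              theta=th, delta=de)
            want = m + th * (best - sub) + de * (best - m)
            np.testing.assert_allclose(out, want, atol=1e-12)

    def test_beta_one_resamples_uniform_within_bounds(self):
        rng = np.random.default_rng(7)
        bounds = GeneBounds([-2.0], [5.0])
        arch = archive_with([0.0], 0.0, [1.0], 1.0)
        draws = np.array([
            ed_mutation(np.array([3.0]), arch, bounds, beta=1.0, rng=rng)[0]
            for _ in range(10_000)])
        assert draws.min() >= -2.0 and draws.max() <= 5.0
        stat = kstest(draws, "uniform", args=(-2.0, 7.0))
        assert stat.pvalue > 0.01

    def test_converged_archive_is_fixed_point_at_beta_zero(self):
        m = np.array([1.5, -0.5, 2.0])
        arch = HistoryArchive()
        arch.best = m.copy()
        arch.best_fitness = 0.0
        arch.sub = m.copy()
        arch.sub_fitness = 0.0
        bounds = GeneBounds(np.full(3, -10.0), np.full(3, 10.0))
        out = ed_mutation(m, arch, bounds, beta=0.0,
                          rng=np.random.default_rng(3))
        np.testing.assert_allclose(out, m, atol=1e-12)

    def test_empty_archive_falls_back_to_resampling(self):
        rng = np.random.default_rng(11)
        bounds = GeneBounds([0.0], [1.0])
        out = ed_mutation(np.array([0.5]), HistoryArchive(), bounds,
                          beta=0.0, rng=rng)  # beta 0 would mean branch 2
        assert 0.0 <= out[0] <= 1.0

    def test_invalid_beta_rejected(self):
        bounds = GeneBounds([0.0], [1.0])
        with pytest.raises(ValueError):
            ed_mutation(np.array([0.5]), HistoryArchive(), bounds, beta=1.5,
                        rng=np.random.default_rng(0))

    def test_outputs_respect_pose_invariants(self, rng):
        topo = make_chain_ligand(3)
        space = docking_space(topo, 4.0)
        for _ in range(200):
            beta = float(rng.uniform())
            arch = archive_with(space.sample(rng), -1.0, space.sample(rng), 0.0)
            out = ed_mutation(space.sample(rng), arch, space.bounds, beta,
                              rng, space=space)
            assert space.bounds.contains(out, atol=1e-12)
            assert abs(np.linalg.norm(out[space.quaternion]) - 1.0) < 1e-9
            tors = out[space.torsions]
            assert np.all(tors >= -180.0) and np.all(tors < 180.0)

    def test_rate_gating_leaves_unhit_genes_untouched(self):
        rng = np.random.default_rng(5)
        bounds = GeneBounds(np.full(50, -1.0), np.full(50, 1.0))
        m = np.zeros(50)
        arch = archive_with(np.full(50, 0.5), 0.0, np.full(50, -0.5), 1.0)
        out = ed_mutation(m, arch, bounds, beta=0.1, rng=rng, rate=0.1)
        assert np.sum(out != m) < 25  # most genes untouched at 10% rate


class TestTwoPointCrossover:
    def test_full_span_cuts_swap_whole_genomes(self, rng):
        a, b = np.arange(5.0), np.arange(5.0) + 10
        ca, cb = two_point_crossover(a, b, rng, cuts=(0, 5))
        np.testing.assert_array_equal(ca, b)
        np.testing.assert_array_equal(cb, a)

    def test_identical_parents_produce_identical_children(self, rng):
        a = np.arange(6.0)
        ca, cb = two_point_crossover(a, a.copy(), rng)
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, a)

    def test_exhaustive_cut_pairs_match_hand_enumeration(self, rng):
        n = 6
        a = np.arange(n, dtype=float)  # integer-tagged loci
        b = np.arange(n, dtype=float) + 100
        for c1 in range(n + 1):
            for c2 in range(c1, n + 1):
                ca, cb = two_point_crossover(a, b, rng, cuts=(c1, c2))
                for locus in range(n):
                    if c1 <= locus < c2:  # middle segment swaps
                        assert ca[locus] == b[locus]
                        assert cb[locus] == a[locus]
                    else:
                        assert ca[locus] == a[locus]
                        assert cb[locus] == b[locus]
                    # per-locus multiset conservation
                    assert {ca[locus], cb[locus]} == {a[locus], b[locus]}

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            two_point_crossover(np.zeros(3), np.zeros(4), rng)


class TestSelection:
    def test_single_individual_always_selected(self, rng):
        pop = [Individual(np.zeros(2), fitness=1.0)]
        assert proportional_selection(pop, rng, n_picks=5) == [0] * 5

    def test_rank_weights_give_three_to_one_ratio(self):
        # 3 individuals -> linear rank weights 3:2:1; compare best vs worst
        rng = np.random.default_rng(2)
        pop = [Individual(np.zeros(1), fitness=f) for f in (-5.0, 2.0, 9.0)]
        picks = proportional_selection(pop, rng, n_picks=30_000)
        counts = np.bincount(picks, minlength=3)
        ratio = counts[0] / counts[2]
        # expected 3.0; binomial noise at n=30k stays well within +-0.3
        assert 2.7 < ratio < 3.3

    def test_equal_fitnesses_sample_uniformly(self):
        rng = np.random.default_rng(3)
        pop = [Individual(np.zeros(1), fitness=1.0) for _ in range(4)]
        picks = proportional_selection(pop, rng, n_picks=40_000)
        freqs = np.bincount(picks, minlength=4) / 40_000
        assert np.all(np.abs(freqs - 0.25) < 0.02)


class TestCeCrossover:
    def test_single_elite_and_its_parents_enter_next_population(self, rng):
        n = 10
        pop = []
        for i in range(n):
            ind = Individual(rng.normal(size=4), fitness=float(i),
                             father=rng.normal(size=4),
                             mother=rng.normal(size=4))
            pop.append(ind)
        arch = HistoryArchive()
        out = ce_crossover(pop, arch, elite_fraction=0.1, rng=rng,
                           generation=3)
        assert len(out) == n
        elite = pop[0]  # lowest fitness
        genomes = [ind.genome for ind in out]
        for target in (elite.genome, elite.father, elite.mother):
            assert any(np.array_equal(g, target) for g in genomes)
        assert len([r for r in arch.elites if r.generation == 3]) == 1
        rec = arch.elites[0]
        assert rec.fitness == elite.fitness
        np.testing.assert_array_equal(rec.father, elite.father)

    def test_never_crossed_elite_records_itself_as_both_parents(self, rng):
        pop = [Individual(rng.normal(size=3), fitness=float(i))
               for i in range(10)]
        arch = HistoryArchive()
        ce_crossover(pop, arch, 0.1, rng)
        rec = arch.elites[0]
        np.testing.assert_array_equal(rec.father, rec.genome)
        np.testing.assert_array_equal(rec.mother, rec.genome)

    def test_clone_population_stays_clonal(self, rng):
        g = np.array([1.0, 2.0, 3.0])
        pop = [Individual(g.copy(), fitness=5.0) for _ in range(8)]
        out = ce_crossover(pop, HistoryArchive(), 0.125, rng)
        for ind in out:
            np.testing.assert_array_equal(ind.genome, g)

    def test_population_size_is_preserved(self, rng):
        for n in (10, 21, 50):
            pop = [Individual(rng.normal(size=5), fitness=float(i))
                   for i in range(n)]
            out = ce_crossover(pop, HistoryArchive(), 0.1, rng)
            assert len(out) == n

    def test_contract_violations_rejected(self, rng):
        one = [Individual(np.zeros(2), fitness=0.0)]
        with pytest.raises(ValueError):
            ce_crossover(one, HistoryArchive(), 0.1, rng)
        pop = [Individual(np.zeros(2), fitness=float(i)) for i in range(4)]
        with pytest.raises(ValueError):
            ce_crossover(pop, HistoryArchive(), 0.7, rng)


class TestSolisWets:
    @staticmethod
    def _quadratic(center):
        bounds = GeneBounds([-5.12], [5.12])
        return ObjectiveFunction(lambda x: float((x[0] - center) ** 2),
                                 GenomeSpace(bounds))

    def test_zero_steps_returns_genome_unchanged(self, rng):
        obj = self._quadratic(1.0)
        x0 = np.array([3.0])
        x, fx, used = solis_wets_search(x0, obj, rng, max_steps=0)
        np.testing.assert_array_equal(x, x0)
        assert used == 1  # the single initial evaluation

    def test_converges_to_quadratic_minimum_over_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            obj = self._quadratic(center=-2.0)
            x, fx, _ = solis_wets_search(np.array([4.0]), obj, rng,
                                         max_steps=200)
            assert abs(x[0] + 2.0) < 0.05

    def test_returned_fitness_never_exceeds_start(self, rng):
        obj = self._quadratic(0.0)
        x0 = np.array([2.5])
        f0 = obj(x0)
        x, fx, _ = solis_wets_search(x0, obj, rng, max_steps=50, f0=f0)
        assert fx <= f0

    def test_evaluation_count_is_reported_exactly(self, rng):
        obj = self._quadratic(0.0)
        before = obj.n_evals
        _, _, used = solis_wets_search(np.array([2.0]), obj, rng,
                                       max_steps=30)
        assert obj.n_evals - before == used

    def test_respects_eval_cap(self, rng):
        obj = self._quadratic(0.0)
        _, _, used = solis_wets_search(np.array([2.0]), obj, rng,
                                       max_steps=1000, max_evals=17)
        assert used <= 17


class TestCauchyMutation:
    def test_outputs_stay_in_bounds(self, rng):
        bounds = GeneBounds(np.full(6, -2.0), np.full(6, 2.0))
        for _ in range(100):
            out = cauchy_mutation(rng.uniform(-2, 2, 6), bounds, rng,
                                  rate=0.5)
            assert bounds.contains(out)

    def test_zero_rate_is_identity(self, rng):
        bounds = GeneBounds(np.full(4, -1.0), np.full(4, 1.0))
        v = rng.uniform(-1, 1, 4)
        np.testing.assert_array_equal(
            cauchy_mutation(v, bounds, rng, rate=0.0), v)


class TestHistoryArchive:
    def test_tracks_best_and_distinct_second_best(self):
        a = HistoryArchive()
        a.observe(np.array([1.0]), 5.0)
        assert not a.ready
        a.observe(np.array([2.0]), 3.0)
        assert a.ready
        assert a.best_fitness == 3.0 and a.sub_fitness == 5.0
        a.observe(np.array([3.0]), 4.0)  # new second best
        assert a.sub_fitness == 4.0
        a.observe(np.array([2.0]), 3.0)  # re-seeing the best is not distinct
        assert a.sub_fitness == 4.0
        assert a.best_fitness <= a.sub_fitness
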