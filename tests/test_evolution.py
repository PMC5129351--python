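"""Fitness components, genetic operators, and the generational loop."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gepqsar import (
    DescriptorTable,
    GEPConfig,
    Population,
    RuleFitnessInputs,
    arithmetic_set,
    compl,
    consig,
    coverage_counts,
    decode,
    evolve,
    fitness,
    mutate,
    random_chromosome,
    recombine,
    roulette_select,
    rule_fitness,
    transpose,
)
from gepqsar.karva import Chromosome


def _tree(tokens, head, terminals=("x1", "x2", "x3")):
    fset = arithmetic_set(terminals)
    return decode(Chromosome(head, tuple(tokens), fset))


@pytest.fixture
def four_row_table():
    frame = pd.DataFrame({"x1": [6.0, 7.0, 1.0, 9.0]})
    return DescriptorTable(np.arange(1, 5), frame, np.array([1, 1, 0, 0]))


class TestCoverage:
    def test_threshold_rule_counts(self, four_row_table):
        # rule x1 - 5 fires on x1 in {6, 7, 9}
        fset = arithmetic_set(["x1"], constants=("5",))
        rule = decode(Chromosome(1, ("-", "x1", "5"), fset))
        f = coverage_counts(rule, four_row_table)
        assert (f.p_cov, f.n_cov, f.p_tot, f.n_tot) == (2, 1, 2, 2)

    def test_constant_rules(self, four_row_table):
        fset = arithmetic_set(["x1"], constants=("0", "1"))
        never = decode(Chromosome(1, ("0", "0", "0"), fset))
        always = decode(Chromosome(1, ("1", "1", "1"), fset))
        f0 = coverage_counts(never, four_row_table)
        f1 = coverage_counts(always, four_row_table)
        assert (f0.p_cov, f0.n_cov) == (0, 0)
        assert (f1.p_cov, f1.n_cov) == (f1.p_tot, f1.n_tot)

    def test_single_class_rejected(self):
        t = DescriptorTable([1, 2], pd.DataFrame({"x1": [1.0, 2.0]}), [1, 1])
        rule = _tree(("x1", "x1", "x1"), 1, ("x1",))
        with pytest.raises(ValueError, match="both classes"):
            coverage_counts(rule, t)


class TestSignificanceAndCompleteness:
    @pytest.mark.parametrize("p,n,P,N,expected", [
        (10, 0, 10, 10, 0.25),     # perfect rule
        (0, 5, 10, 10, -0.25),     # anti-rule
        (5, 5, 10, 10, 0.0),       # precision equals base rate
        (0, 0, 10, 10, 0.0),       # covers nothing: defined as 0
    ])
    def test_consig_examples(self, p, n, P, N, expected):
        assert consig(RuleFitnessInputs(p, n, P, N)) == pytest.approx(expected)

    @pytest.mark.parametrize("p,P,expected", [(4, 4, 1.0), (0, 4, 0.0), (3, 4, 0.75)])
    def test_compl_examples(self, p, P, expected):
        assert compl(RuleFitnessInputs(p, 0, P, 1)) == pytest.approx(expected)

    def test_brute_force_grid_matches_direct_fractions(self):
        """Exhaustive check of both components against literal fraction
        arithmetic over every coverage grid with P, N <= 12."""
        for P, N in itertools.product(range(1, 13), range(1, 13)):
            base = P / (P + N)
            for p, n in itertools.product(range(P + 1), range(N + 1)):
                f = RuleFitnessInputs(p, n, P, N)
                expected = 0.0 if p + n == 0 else (p / (p + n) - base) * base
                assert consig(f) == pytest.approx(expected, abs=1e-15)
                assert compl(f) == pytest.approx(p / P, abs=1e-15)

    def test_consig_bound_attained_only_by_pure_rules(self):
        """consig <= base*(1-base), equality iff the rule covers only
        positives; brute force over all grids with P, N <= 12."""
        for P, N in itertools.product(range(1, 13), range(1, 13)):
            base = P / (P + N)
            bound = base * (1 - base)
            for p, n in itertools.product(range(P + 1), range(N + 1)):
                c = consig(RuleFitnessInputs(p, n, P, N))
                assert c <= bound + 1e-12
                if abs(c - bound) < 1e-12:
                    assert n == 0 and p >= 1

    def test_printed_composition_is_degenerate(self):
        # compl <= 1 means ln(compl - 1) always hits the protected branch
        for p in range(11):
            f = RuleFitnessInputs(p, 2, 10, 10)
            assert rule_fitness(f) == 0.0

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            RuleFitnessInputs(5, 0, 4, 4)


class TestFitness:
    def test_hits_based_counts_both_classes(self, four_row_table):
        fset = arithmetic_set(["x1"], constants=("5",))
        rule = decode(Chromosome(1, ("-", "x1", "5"), fset))
        # predicts 1,1,0,1 against labels 1,1,0,0 -> 3 hits
        assert fitness(rule, four_row_table, "hits_based") == 3.0

    def test_as_printed_zero_when_consig_negative(self, four_row_table):
        fset = arithmetic_set(["x1"], constants=("5",))
        anti = decode(Chromosome(1, ("-", "5", "x1"), fset))  # fires on the negative
        assert fitness(anti, four_row_table, "as_printed") == 0.0

    def test_perfect_rule_hits_equals_n(self, toy_table):
        rule = _tree(("+", "x1", "x2"), 1)
        assert fitness(rule, toy_table, "hits_based") == toy_table.n


class TestSelection:
    def test_proportional_sampling(self, rng, abcd_set):
        a = random_chromosome(abcd_set, 3, rng)
        b = random_chromosome(abcd_set, 3, rng)
        pop = Population([(a, 3.0), (b, 1.0)])
        draws = sum(roulette_select(pop, rng) is a for _ in range(100_000))
        # binomial 3-sigma band around p = 0.75
        sigma = np.sqrt(0.75 * 0.25 * 100_000)
        assert abs(draws - 75_000) < 3 * sigma

    def test_all_zero_fitness_uniform(self, rng, abcd_set):
        a = random_chromosome(abcd_set, 3, rng)
        b = random_chromosome(abcd_set, 3, rng)
        pop = Population([(a, 0.0), (b, 0.0)])
        draws = sum(roulette_select(pop, rng) is a for _ in range(20_000))
        sigma = np.sqrt(0.25 * 20_000)
        assert abs(draws - 10_000) < 4 * sigma

    def test_single_member_always_selected(self, rng, abcd_set):
        c = random_chromosome(abcd_set, 3, rng)
        pop = Population([(c, 0.0)])
        assert roulette_select(pop, rng) is c

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            roulette_select(Population([]), rng)


class TestOperators:
    def test_mutation_rate_zero_is_identity(self, rng, abcd_set):
        c = random_chromosome(abcd_set, 5, rng)
        assert mutate(c, 0.0, rng) == c

    def test_mutation_rate_one_stays_valid(self, rng, abcd_set):
        c = random_chromosome(abcd_set, 5, rng)
        m = mutate(c, 1.0, rng)
        assert m.is_valid

    def test_ris_without_functions_is_identity(self, rng, abcd_set):
        c = Chromosome(3, ("a", "b", "c", "d", "a", "b", "c"), abcd_set)
        assert transpose(c, "ris", rng) == c

    def test_gene_transposition_is_noop(self, rng, abcd_set):
        c = random_chromosome(abcd_set, 5, rng)
        assert transpose(c, "gene", rng) == c

    def test_identical_parents_identical_children(self, rng, abcd_set):
        c = random_chromosome(abcd_set, 5, rng)
        for mode in ("one_point", "two_point", "gene"):
            ca, cb = recombine(c, c, mode, rng)
            assert ca == c and cb == c

    def test_one_point_cut_zero_swaps_parents(self, abcd_set):
        class ZeroCut:
            def integers(self, *a, **k):
                return 0
        a = Chromosome(2, ("+", "a", "b", "a", "b"), abcd_set)
        b = Chromosome(2, ("-", "c", "d", "c", "d"), abcd_set)
        ca, cb = recombine(a, b, "one_point", ZeroCut())
        assert ca == b and cb == a

    def test_shape_mismatch_rejected(self, rng, abcd_set):
        a = random_chromosome(abcd_set, 3, rng)
        b = random_chromosome(abcd_set, 4, rng)
        with pytest.raises(ValueError, match="head length"):
            recombine(a, b, "one_point", rng)

    def test_operator_closure_ten_thousand_trials(self, rng, abcd_set):
        """Every operator maps valid genotypes to valid genotypes."""
        for _ in range(2500):
            h = int(rng.integers(1, 10))
            a = random_chromosome(abcd_set, h, rng)
            b = random_chromosome(abcd_set, h, rng)
            assert mutate(a, 0.2, rng).is_valid
            assert transpose(a, "is", rng).is_valid
            assert transpose(a, "ris", rng).is_valid
            ca, cb = recombine(a, b, ("one_point", "two_point", "gene")[int(rng.integers(3))], rng)
            assert ca.is_valid and cb.is_valid


class TestEvolve:
    def test_recovers_planted_linear_rule(self, toy_table):
        cfg = GEPConfig(population_size=60, generations=120, seed=5,
                        stop_at_fitness=float(toy_table.n))
        res = evolve(toy_table, cfg)
        assert res.best_fitness >= 0.95 * toy_table.n

    def test_zero_generations_returns_initial_best(self, toy_table):
        cfg = GEPConfig(population_size=30, generations=0, seed=2)
        res = evolve(toy_table, cfg)
        assert len(res.history) == 1
        assert res.history[0]["generation"] == 0
        assert res.best_fitness == res.history[0]["best_fitness"]

    def test_fixed_seed_reproduces_trace(self, toy_table):
        cfg = GEPConfig(population_size=30, generations=25, seed=11)
        r1 = evolve(toy_table, cfg)
        r2 = evolve(toy_table, cfg)
        assert r1.history == r2.history
        assert r1.best_chromosome == r2.best_chromosome

    def test_best_ever_nondecreasing_with_elitism(self, toy_table):
        cfg = GEPConfig(population_size=30, generations=40, seed=3, elitism=1)
        res = evolve(toy_table, cfg)
        # the carried elite is rescored deterministically, so the
        # generation best can never fall
        best = [h["best_fitness"] for h in res.history]
        assert np.all(np.diff(best) >= 0)

    def test_single_class_rejected(self):
        t = DescriptorTable([1, 2], pd.DataFrame({"x1": [0.0, 1.0]}), [0, 0])
        with pytest.raises(ValueError, match="both classes"):
            evolve(t, GEPConfig(population_size=10, generations=1, seed=0))

    def test_history_export_columns(self, toy_table):
        res = evolve(toy_table, GEPConfig(population_size=20, generations=5, seed=1))
        frame = res.history_frame()
        assert list(frame.columns) == ["generation", "best_fitness", "mean_fitness"]
        assert len(frame) == 6
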