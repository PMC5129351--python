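"""Generational evolution of classification rules.

A population of Karva chromosomes is scored against a labeled descriptor
table, elites are carried over unchanged, and the remainder of each new
generation is bred by fitness-proportionate (roulette) selection followed
by mutation, insertion-sequence (IS) and root-insertion-sequence (RIS)
transposition, and one-point / two-point / whole-genotype recombination.
A compound is predicted positive when the decoded rule evaluates above
zero on its descriptors.

Two fitness modes are provided.  ``hits_based`` (the default used for
search) counts correctly classified training compounds.  ``as_printed``
reproduces the published rule-significance composition verbatim:

    fitness(R) = 0                                if consig(R) < 0
               = consig(R) * ln(compl(R) - 1)     otherwise

with  consig(R) = (p/(p+n) - P/(P+N)) * P/(P+N)  and  compl(R) = p/P,
where p, n are the positive/negative compounds covered by the rule
(value > 0) and P, N the training totals.  Because compl <= 1 always,
ln(compl - 1) is never defined on the reals; under the package-wide
protected log (argument <= 0 -> 0) the printed composition is therefore
identically zero.  It is kept, behind the flag, exactly as stated, as a
fidelity reference rather than a usable objective -- the components
consig and compl are themselves well-defined and fully tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from .data import DescriptorTable
from .karva import (
    Chromosome,
    ExpressionTree,
    FunctionSet,
    arithmetic_set,
    decode,
    extended_set,
    p_log,
    random_chromosome,
)

__all__ = [
    "GEPConfig",
    "RuleFitnessInputs",
    "Population",
    "EvolutionResult",
    "coverage_counts",
    "consig",
    "compl",
    "rule_fitness",
    "fitness",
    "roulette_select",
    "mutate",
    "transpose",
    "recombine",
    "evolve",
]

_MAX_SEGMENT = 3  # transposition segments are short, 1..3 symbols


@dataclass(frozen=True)
class GEPConfig:
    """Run parameters for the evolutionary search.

    Rates are probabilities: ``rate_mutation`` applies per symbol position,
    transposition rates per individual, recombination rates per parent
    pair.  ``fitness_mode`` selects the search objective (see module
    docstring).  The whole run is reproducible from ``seed``.
    """

    population_size: int = 100
    generations: int = 500
    head_length: int = 7
    rate_mutation: float = 0.05
    rate_is: float = 0.1
    rate_ris: float = 0.1
    rate_gene: float = 0.1
    rate_one_point: float = 0.3
    rate_two_point: float = 0.3
    rate_gene_recomb: float = 0.1
    elitism: int = 1
    seed: int = 0
    fitness_mode: str = "hits_based"
    function_set: str = "arithmetic"
    constants: tuple[str, ...] = ()
    stop_at_fitness: float | None = None

    def __post_init__(self):
        for name in ("rate_mutation", "rate_is", "rate_ris", "rate_gene",
                     "rate_one_point", "rate_two_point", "rate_gene_recomb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 1 or self.head_length < 1 or self.generations < 0:
            raise ValueError("population_size, head_length >= 1 and generations >= 0 required")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be < population_size")
        if self.fitness_mode not in ("hits_based", "as_printed"):
            raise ValueError(f"unknown fitness_mode {self.fitness_mode!r}")
        if self.function_set not in ("arithmetic", "extended"):
            raise ValueError(f"unknown function_set {self.function_set!r}")

    def build_function_set(self, terminals) -> FunctionSet:
        builder = arithmetic_set if self.function_set == "arithmetic" else extended_set
        return builder(terminals, self.constants)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["constants"] = list(d["constants"])
        return d


@dataclass(frozen=True)
class RuleFitnessInputs:
    """Coverage counts of a rule on a labeled table."""

    p_cov: int   # positives the rule covers (value > 0)
    n_cov: int   # negatives the rule covers
    p_tot: int   # positives in the training set
    n_tot: int   # negatives in the training set

    def __post_init__(self):
        if not (0 <= self.p_cov <= self.p_tot and 0 <= self.n_cov <= self.n_tot):
            raise ValueError("coverage counts out of range")
        if self.p_tot + self.n_tot < 1:
            raise ValueError("empty training set")


@dataclass
class Population:
    members: list[tuple[Chromosome, float]]
    generation: int = 0

    def fitnesses(self) -> np.ndarray:
        return np.array([f for _, f in self.members], dtype=float)

    def best(self) -> tuple[Chromosome, float]:
        i = int(np.argmax(self.fitnesses()))
        return self.members[i]


def coverage_counts(rule: ExpressionTree, data: DescriptorTable) -> RuleFitnessInputs:
    """Count positives/negatives on which the rule fires (value > 0)."""
    pos, neg = data.class_counts()
    if pos == 0 or neg == 0:
        raise ValueError("training data must contain both classes")
    vals = np.atleast_1d(rule.evaluate(data.env()))
    fired = vals > 0
    y = data.y
    return RuleFitnessInputs(
        p_cov=int((fired & (y == 1)).sum()),
        n_cov=int((fired & (y == 0)).sum()),
        p_tot=pos,
        n_tot=neg,
    )


def consig(f: RuleFitnessInputs) -> float:
    """Rule significance: (precision - base rate) * base rate.

    A rule that covers nothing has significance 0 (the limiting value of
    the precision/base-rate comparison).
    """
    base = f.p_tot / (f.p_tot + f.n_tot)
    covered = f.p_cov + f.n_cov
    if covered == 0:
        return 0.0
    return (f.p_cov / covered - base) * base


def compl(f: RuleFitnessInputs) -> float:
    """Rule completeness: fraction of positives covered, in [0, 1]."""
    if f.p_tot < 1:
        raise ValueError("completeness needs at least one positive")
    return f.p_cov / f.p_tot


def rule_fitness(f: RuleFitnessInputs) -> float:
    """The printed significance/completeness composition (see module doc);
    the inner log is protected, so the value is 0 for any real input."""
    c = consig(f)
    if c < 0:
        return 0.0
    return c * float(p_log(compl(f) - 1.0))


def fitness(rule: ExpressionTree, data: DescriptorTable, mode: str = "hits_based") -> float:
    """Score a rule on a labeled table; finite and >= 0 in both modes."""
    if mode == "hits_based":
        pos, neg = data.class_counts()
        if pos == 0 or neg == 0:
            raise ValueError("training data must contain both classes")
        vals = np.atleast_1d(rule.evaluate(data.env()))
        return float(((vals > 0).astype(int) == data.y).sum())
    if mode == "as_printed":
        return rule_fitness(coverage_counts(rule, data))
    raise ValueError(f"unknown fitness mode {mode!r}")


# ---------------------------------------------------------------------------
# genetic operators (all closed over valid chromosomes)

def roulette_select(pop: Population, rng: np.random.Generator) -> Chromosome:
    """Fitness-proportionate selection; uniform fallback when all zero."""
    if not pop.members:
        raise ValueError("empty population")
    fits = pop.fitnesses()
    total = fits.sum()
    if total <= 0:
        return pop.members[int(rng.integers(len(pop.members)))][0]
    return pop.members[int(rng.choice(len(pop.members), p=fits / total))][0]


def mutate(c: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Point mutation: each position independently resampled with
    probability ``rate`` from its legal alphabet (head: functions and
    terminals; tail: terminals only)."""
    if rate <= 0:
        return c
    fset = c.function_set
    head_pool, tail_pool = fset.head_pool, fset.terminal_pool
    hits = rng.random(len(c.symbols)) < rate
    if not hits.any():
        return c
    symbols = list(c.symbols)
    for i in np.flatnonzero(hits):
        pool = head_pool if i < c.head_length else tail_pool
        symbols[i] = pool[rng.integers(len(pool))]
    return Chromosome(c.head_length, tuple(symbols), fset)


def _insert_into_head(c: Chromosome, segment: tuple[str, ...], at: int) -> Chromosome:
    """Insert a segment into the head at ``at``, shifting right and
    truncating at the head boundary; the tail is untouched."""
    h = c.head_length
    head = list(c.symbols[:h])
    new_head = (head[:at] + list(segment) + head[at:])[:h]
    return Chromosome(h, tuple(new_head) + c.symbols[h:], c.function_set)


def transpose(c: Chromosome, mode: str, rng: np.random.Generator) -> Chromosome:
    """IS / RIS / gene transposition.

    IS copies a short random segment to a random non-root head position.
    RIS requires the segment to start with a function symbol and inserts
    it at the head root.  Gene transposition is the identity for
    single-gene genotypes and is recorded as a no-op.
    """
    h = c.head_length
    if mode == "gene":
        return c
    if mode == "is":
        if h < 2:
            return c
        length = int(rng.integers(1, _MAX_SEGMENT + 1))
        start = int(rng.integers(len(c.symbols)))
        segment = c.symbols[start:start + length]
        at = int(rng.integers(1, h))          # never the root
        # tail symbols may enter the head: terminals are legal there
        return _insert_into_head(c, segment, at)
    if mode == "ris":
        fset = c.function_set
        scan_from = int(rng.integers(h))
        start = next((i for i in range(scan_from, h)
                      if fset.lookup(c.symbols[i]) is not None), None)
        if start is None:
            return c
        length = int(rng.integers(1, _MAX_SEGMENT + 1))
        segment = c.symbols[start:min(start + length, h)]
        return _insert_into_head(c, segment, 0)
    raise ValueError(f"unknown transposition mode {mode!r}")


def recombine(a: Chromosome, b: Chromosome, mode: str,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Exchange genetic material between two shape-compatible parents.

    Cut indices are shared by both parents, so tail positions only ever
    receive tail material and both children stay valid.
    """
    if a.head_length != b.head_length or a.function_set.spec() != b.function_set.spec():
        raise ValueError("parents must share head length and function set")
    L = len(a.symbols)
    sa, sb = list(a.symbols), list(b.symbols)
    if mode == "one_point":
        cut = int(rng.integers(0, L + 1))
        ca = sa[:cut] + sb[cut:]
        cb = sb[:cut] + sa[cut:]
    elif mode == "two_point":
        i, j = sorted(int(x) for x in rng.integers(0, L + 1, size=2))
        ca = sa[:i] + sb[i:j] + sa[j:]
        cb = sb[:i] + sa[i:j] + sb[j:]
    elif mode == "gene":
        ca, cb = sb, sa               # whole-genotype swap (single gene)
    else:
        raise ValueError(f"unknown recombination mode {mode!r}")
    return (Chromosome(a.head_length, tuple(ca), a.function_set),
            Chromosome(a.head_length, tuple(cb), a.function_set))


# ---------------------------------------------------------------------------
# the generational loop

@dataclass
class EvolutionResult:
    best_chromosome: Chromosome
    best_fitness: float
    history: list[dict]                 # generation, best_fitness, mean_fitness
    generations_run: int

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)


def evolve(data: DescriptorTable, config: GEPConfig,
           rng: np.random.Generator | None = None,
           score: Callable[[ExpressionTree, DescriptorTable], float] | None = None,
           ) -> EvolutionResult:
    """Run the generational loop and return the best-ever individual.

    Each generation: score every chromosome, carry ``elitism`` elites
    unchanged, refill by roulette selection, then apply mutation,
    transposition and recombination at the configured rates.  With a fixed
    seed the full trace is reproducible.  ``score`` may override the
    fitness function (it receives the decoded tree and the data).
    """
    pos, neg = data.class_counts()
    if pos == 0 or neg == 0:
        raise ValueError("training data must contain both classes")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fset = config.build_function_set(data.descriptors)
    env = data.env()
    y = data.y

    if score is None:
        if config.fitness_mode == "hits_based":
            def score_chrom(chrom: Chromosome) -> float:
                vals = np.atleast_1d(decode(chrom).evaluate(env))
                return float(((vals > 0).astype(int) == y).sum())
        else:
            def score_chrom(chrom: Chromosome) -> float:
                return rule_fitness(coverage_counts(decode(chrom), data))
    else:
        def score_chrom(chrom: Chromosome) -> float:
            return float(score(decode(chrom), data))

    chroms = [random_chromosome(fset, config.head_length, rng)
              for _ in range(config.population_size)]
    fits = [score_chrom(c) for c in chroms]
    pop = Population(list(zip(chroms, fits)), generation=0)

    best_c, best_f = pop.best()
    history = [{"generation": 0, "best_fitness": best_f,
                "mean_fitness": float(np.mean(fits))}]

    gens_run = 0
    for gen in range(1, config.generations + 1):
        if config.stop_at_fitness is not None and best_f >= config.stop_at_fitness:
            break
        order = np.argsort([-f for f in fits], kind="stable")
        elites = [chroms[i] for i in order[:config.elitism]]

        n_fill = config.population_size - len(elites)
        parents = [roulette_select(pop, rng) for _ in range(n_fill)]
        parents = [mutate(p, config.rate_mutation, rng) for p in parents]
        parents = [transpose(p, "is", rng) if rng.random() < config.rate_is else p
                   for p in parents]
        parents = [transpose(p, "ris", rng) if rng.random() < config.rate_ris else p
                   for p in parents]
        parents = [transpose(p, "gene", rng) if rng.random() < config.rate_gene else p
                   for p in parents]
        for i in range(0, n_fill - 1, 2):
            a, b = parents[i], parents[i + 1]
            if rng.random() < config.rate_one_point:
                a, b = recombine(a, b, "one_point", rng)
            if rng.random() < config.rate_two_point:
                a, b = recombine(a, b, "two_point", rng)
            if rng.random() < config.rate_gene_recomb:
                a, b = recombine(a, b, "gene", rng)
            parents[i], parents[i + 1] = a, b

        chroms = elites + parents
        fits = [score_chrom(c) for c in chroms]
        pop = Population(list(zip(chroms, fits)), generation=gen)
        gen_best_c, gen_best_f = pop.best()
        if gen_best_f > best_f:
            best_c, best_f = gen_best_c, gen_best_f
        history.append({"generation": gen, "best_fitness": gen_best_f,
                        "mean_fitness": float(np.mean(fits))})
        gens_run = gen

    return EvolutionResult(best_c, best_f, history, gens_run)
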