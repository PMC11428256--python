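"""CGEMGA: genetic-algorithm optimization of conserved-module seeds.

Instead of CGEM's purely random seed draws, a population of chromosomes —
each encoding a seed as a fixed-length, duplicate-free vector of sample
indices [c, d1, ..., d_{s_d-1}] — is evolved under a Mean Squared Residue
fitness. The module induced by each chromosome is built exactly as in the
baseline search. Tournament selection, single-point crossover and
per-locus mutation generate offspring; elitism preserves the best seeds,
so best fitness is monotone non-increasing. Several independent restarts
are run and their best modules reported, lowest MSR first.

Constraint handling
-------------------
Raw MSR minimization is downward-biased toward tiny submatrices: under
i.i.d. noise the expected MSR of an |I| × |J| block is proportional to
(1 − 1/|I|)(1 − 1/|J|), and a single-gene module scores exactly 0 by
algebra, so an unconstrained search collapses onto degenerate minima. The
search therefore treats a minimum module gene count (``min_genes``) as a
constraint, handled two ways:

* a module must have at least ``min_genes`` genes and cover at least a
  fraction α of the samples to be *admissible* (reportable). During
  evolution these floors are graded penalties, not walls: an undersized
  or under-covering module scores ``msr + deficit × scale`` where
  ``deficit`` counts the missing genes plus missing samples and ``scale``
  is the MSR of the whole matrix — large relative to any coherent
  module's score. The graded form keeps the fitness landscape connected
  (a seed two planted samples short of a conserved block is still
  rewarded for every conserved gene it has), which is what lets
  crossover and mutation climb toward the block. Empty modules get an
  infinite sentinel outright.

Admissible modules compete on their *size-adjusted* MSR,
``msr / ((1 − 1/|I|)(1 − 1/|J|))``. The divisor is the exact size
dependence of the expected MSR of an i.i.d.-noise block, so the adjusted
score is size-unbiased: a submatrix of a coherent module no longer
outscores the full module merely by being smaller, while every genuinely
incoherent row or column it absorbs still raises the score. Exact ties
(e.g. perfectly additive modules, adjusted score 0) are broken by larger
|G| × |C|, the same tie-break used for final cross-restart selection.
Reported module records always carry the raw MSR.

The floors themselves guard against a second failure mode: minimizing an
*empirical* variance score over adaptively chosen row/column subsets is
downward-biased, and the bias grows as the subset shrinks (the estimator's
relative spread is ~sqrt(2/df) with df = (|I|−1)(|J|−1)). The GA default
α = 0.25 therefore asks reported modules to cover a recurrent quarter of
the cohort — both the scale of expression subgroups the method is aimed
at and a cap on how far the search can prune samples to flatter its own
score. The baseline CGEM search keeps the permissive α = 0.05 default:
its max-|G| objective has no incentive to shrink coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cgem import ConservedModule, Seed, build_module
from .matrix import DiscretizedMatrix, ExpressionMatrix
from .msr import Bicluster, msr as _msr

__all__ = [
    "Chromosome",
    "GAParams",
    "ConvergenceTrace",
    "GAResult",
    "initialize_population",
    "evaluate_fitness",
    "evolve_generation",
    "run_cgemga",
    "size_adjusted_msr",
    "matrix_scale",
]

SENTINEL = float("inf")


@dataclass
class Chromosome:
    """A seed genotype (sample indices, position 0 is the seed sample c)
    with its fitness (+inf sentinel until evaluated or when the module is
    discarded; equals the module's MSR when the module is admissible)."""

    genotype: np.ndarray
    fitness: float = SENTINEL
    module: ConservedModule | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.int64)
        if np.unique(self.genotype).size != self.genotype.size:
            raise ValueError("duplicate sample index in genotype")

    @property
    def size(self) -> int:
        return self.module.size if self.module is not None else 0

    def seed(self) -> Seed:
        return Seed(int(self.genotype[0]), frozenset(int(x) for x in self.genotype))

    def key(self) -> tuple[float, int]:
        """Lexicographic fitness key: (fitness, -|G|·|C|); lower is better."""
        return (self.fitness, -self.size)


@dataclass
class GAParams:
    """Genetic-algorithm settings (standard operator scheme, all exposed).

    population_size (n), max_generations (MAX), crossover_prob,
    mutation_prob, elitism_count, tournament_size, patience (early stop
    after this many generations without improvement), alpha and
    discriminating_size (s_d) as in the baseline search, min_genes — the
    minimum |G| for a module to be admissible (default 10: a reported
    expression module should be a multi-gene signature, and the floor is
    what makes MSR minimization well-posed; see module docstring),
    num_restarts (n_s) independent GA runs.

    Defaults size the population (150) so the initial sample of seeds is
    dense enough that some individual already shares most of its samples
    with any conserved block covering an α-worthy sample fraction, and set
    selection pressure (tournament 8) and mutation (0.2 per locus) high
    enough that such an individual's lineage reaches the block within a
    handful of generations — the regime the method is designed around.
    """

    population_size: int = 150
    max_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    elitism_count: int = 1
    tournament_size: int = 8
    patience: int = 10
    alpha: float = 0.25
    discriminating_size: int = 7
    min_genes: int = 10
    num_restarts: int = 10
    rng_seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (1 <= self.elitism_count < self.population_size):
            raise ValueError("elitism_count must be in [1, population_size)")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if not (1 <= self.discriminating_size <= n_samples):
            raise ValueError("discriminating_size must be in [1, M]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")
        if self.num_restarts < 1:
            raise ValueError("num_restarts must be >= 1")


@dataclass
class ConvergenceTrace:
    """Best fitness after each generation (index 0 = initial population).

    With elitism the sequence is non-increasing; generation_of_convergence
    is the first generation already attaining the final best fitness.
    """

    best_fitness_per_generation: list[float]

    @property
    def generation_of_convergence(self) -> int:
        final = self.best_fitness_per_generation[-1]
        for t, f in enumerate(self.best_fitness_per_generation):
            if f == final:
                return t
        return len(self.best_fitness_per_generation) - 1


@dataclass
class GAResult:
    """Modules of all restarts (ascending MSR, size tie-break), the
    convergence trace of the best restart, and bookkeeping."""

    modules: list[ConservedModule]
    trace: ConvergenceTrace | None
    n_evaluations: int
    restart_traces: list[ConvergenceTrace]


def matrix_scale(values: ExpressionMatrix | np.ndarray) -> float:
    """MSR of the entire matrix — the natural score scale of a dataset,
    used as the per-missing-gene penalty unit for undersized modules."""
    arr = values.values if hasattr(values, "values") else np.asarray(values)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        return 1.0
    scale = _msr(arr, Bicluster(np.arange(arr.shape[0]), np.arange(arr.shape[1])))
    return scale if scale > 0 else 1.0


def initialize_population(disc: DiscretizedMatrix, params: GAParams,
                          rng: np.random.Generator) -> list[Chromosome]:
    """n chromosomes with uniformly random duplicate-free genotypes."""
    params.validate(disc.n_samples)
    m = disc.n_samples
    return [Chromosome(rng.choice(m, size=params.discriminating_size, replace=False))
            for _ in range(params.population_size)]


def size_adjusted_msr(module: ConservedModule) -> float:
    """MSR divided by (1 − 1/|I|)(1 − 1/|J|), the size dependence of the
    expected MSR of an i.i.d.-noise block — a size-unbiased coherence
    score for comparing modules of different dimensions."""
    i, j = module.n_genes, module.n_samples
    if i < 2 or j < 2:
        return module.msr  # MSR of a single row/column is identically 0
    return module.msr / ((1.0 - 1.0 / i) * (1.0 - 1.0 / j))


def evaluate_fitness(chromosome: Chromosome, disc: DiscretizedMatrix,
                     values: ExpressionMatrix | np.ndarray,
                     alpha: float, min_genes: int = 10,
                     penalty_scale: float | None = None) -> float:
    """Fitness of the chromosome's induced module.

    Equals the module's size-adjusted MSR when the module is admissible
    (|G| ≥ min_genes, coverage ≥ alpha × M); +inf sentinel when the
    module is empty; raw MSR plus the graded deficit penalty — one
    ``penalty_scale`` unit per missing gene or sample — when it falls
    short of either floor (see module docstring). The raw MSR stays
    available as ``chromosome.module.msr``.
    """
    module = build_module(disc, chromosome.seed(), values)
    chromosome.module = module
    if module.n_genes == 0:
        chromosome.fitness = SENTINEL
        return chromosome.fitness
    min_samples = int(np.ceil(alpha * disc.n_samples))
    deficit = (max(0, min_genes - module.n_genes)
               + max(0, min_samples - module.n_samples))
    if deficit > 0:
        if penalty_scale is None:
            penalty_scale = matrix_scale(values)
        chromosome.fitness = module.msr + deficit * penalty_scale
    else:
        chromosome.fitness = size_adjusted_msr(module)
    return chromosome.fitness


def _repair(genotype: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Replace duplicate indices with uniform draws among unused ones."""
    seen: set[int] = set()
    dup_pos = []
    for pos, g in enumerate(genotype):
        if int(g) in seen:
            dup_pos.append(pos)
        seen.add(int(g))
    if dup_pos:
        unused = np.setdiff1d(np.arange(m), genotype)
        fill = rng.choice(unused, size=len(dup_pos), replace=False)
        genotype = genotype.copy()
        genotype[dup_pos] = fill
    return genotype


def _tournament(population: list[Chromosome], k: int,
                rng: np.random.Generator) -> Chromosome:
    picks = rng.integers(0, len(population), size=k)
    best = population[picks[0]]
    for p in picks[1:]:
        if population[p].key() < best.key():
            best = population[p]
    return best


def evolve_generation(population: list[Chromosome], params: GAParams,
                      rng: np.random.Generator,
                      n_samples: int | None = None) -> list[Chromosome]:
    """One generation: copy elites, then fill with tournament-selected,
    crossed-over, mutated, repaired offspring (fitness unevaluated).

    ``n_samples`` bounds the index range mutation can resample from; when
    omitted it is inferred from the largest index present.
    """
    n = len(population)
    m_hint = n_samples if n_samples is not None else \
        max(int(ch.genotype.max()) for ch in population) + 1
    order = sorted(range(n), key=lambda i: (population[i].key(), i))
    new_pop: list[Chromosome] = [
        Chromosome(population[i].genotype.copy(),
                   population[i].fitness, population[i].module)
        for i in order[:params.elitism_count]
    ]
    s_d = population[0].genotype.size
    while len(new_pop) < n:
        p1 = _tournament(population, params.tournament_size, rng)
        p2 = _tournament(population, params.tournament_size, rng)
        g1, g2 = p1.genotype.copy(), p2.genotype.copy()
        if s_d > 1 and rng.random() < params.crossover_prob:
            point = int(rng.integers(1, s_d))
            g1 = np.concatenate([p1.genotype[:point], p2.genotype[point:]])
            g2 = np.concatenate([p2.genotype[:point], p1.genotype[point:]])
        for g in (g1, g2):
            if len(new_pop) >= n:
                break
            mutate = rng.random(s_d) < params.mutation_prob
            if mutate.any():
                unused = np.setdiff1d(np.arange(m_hint), g)
                for pos in np.flatnonzero(mutate):
                    if unused.size == 0:
                        break
                    pick = int(rng.integers(0, unused.size))
                    old, g[pos] = g[pos], unused[pick]
                    unused[pick] = old
            g = _repair(g, m_hint, rng)
            new_pop.append(Chromosome(g))
    return new_pop


def _is_admissible(ch: Chromosome, params: GAParams, m: int) -> bool:
    return (ch.module is not None
            and ch.module.n_genes >= params.min_genes
            and ch.module.n_samples >= params.alpha * m)


def _run_restart(disc: DiscretizedMatrix, values, params: GAParams,
                 rng: np.random.Generator, scale: float):
    population = initialize_population(disc, params, rng)
    evals = 0
    for ch in population:
        evaluate_fitness(ch, disc, values, params.alpha, params.min_genes, scale)
        evals += 1
    best = min(population, key=lambda ch: ch.key())
    best = Chromosome(best.genotype.copy(), best.fitness, best.module)
    trace = [best.fitness]
    stale = 0
    for _t in range(params.max_generations):
        population = evolve_generation(population, params, rng, disc.n_samples)
        for ch in population:
            if ch.module is None:  # elites keep their evaluation
                evaluate_fitness(ch, disc, values, params.alpha,
                                 params.min_genes, scale)
                evals += 1
        gen_best = min(population, key=lambda ch: ch.key())
        if gen_best.key() < best.key():
            best = Chromosome(gen_best.genotype.copy(), gen_best.fitness,
                              gen_best.module)
            stale = 0
        else:
            stale += 1
        trace.append(best.fitness)
        if stale >= params.patience:
            break
    return best, ConvergenceTrace(trace), evals


def run_cgemga(disc: DiscretizedMatrix,
               values: ExpressionMatrix | np.ndarray,
               params: GAParams | None = None) -> GAResult:
    """Full CGEMGA run: num_restarts independent GA restarts, each evolved
    to convergence (patience) or max_generations.

    Returns the admissible best module of every restart ranked by
    ascending MSR (|G| × |C| breaks ties), the convergence trace of the
    best restart, and the total number of fitness evaluations. Restarts
    whose best module is inadmissible are dropped; if every restart is
    dropped the module list is empty and a warning is emitted (not an
    exception).
    """
    if params is None:
        params = GAParams()
    params.validate(disc.n_samples)
    scale = matrix_scale(values)
    seed_seq = np.random.SeedSequence(params.rng_seed)
    results = []
    total_evals = 0
    traces: list[ConvergenceTrace] = []
    for child in seed_seq.spawn(params.num_restarts):
        best, trace, evals = _run_restart(disc, values, params,
                                          np.random.default_rng(child), scale)
        total_evals += evals
        traces.append(trace)
        if _is_admissible(best, params, disc.n_samples):
            results.append((best, trace))
    if not results:
        warnings.warn("all CGEMGA restarts were discarded by the coverage/size "
                      "filters; no module to report", stacklevel=2)
        return GAResult([], None, total_evals, traces)
    results.sort(key=lambda bt: (bt[0].fitness, -bt[0].size))
    modules = [best.module for best, _ in results]
    return GAResult(modules, results[0][1], total_evals, traces)
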