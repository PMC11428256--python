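"""Baseline CGEM search: conserved modules from seeds, random multistart,
and iterative bicluster extraction by sample removal.

A *seed* is a sample c plus a discriminating subset D of samples (c ∈ D,
|D| = s_d). The module induced by a seed collects every gene whose
discrete state agrees across all of D (paired with its state in c), then
every sample that agrees with c on all of those gene-state pairs. CGEM
draws many seeds uniformly at random, keeps modules covering at least a
fraction α of the samples, and returns the one with the most conserved
genes; successive biclusters are found by removing matched samples and
repeating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .matrix import DiscretizedMatrix, ExpressionMatrix
from .msr import Bicluster, msr

__all__ = [
    "Seed",
    "SearchParams",
    "ConservedModule",
    "build_module",
    "find_largest_module",
    "extract_biclusters",
    "enumerate_seeds",
    "draw_seed",
    "best_module",
]


@dataclass(frozen=True)
class Seed:
    """Seed sample c plus discriminating sample set D (c ∈ D)."""

    seed_sample: int
    discriminating_set: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "discriminating_set",
                           frozenset(int(d) for d in self.discriminating_set))
        if self.seed_sample not in self.discriminating_set:
            raise ValueError("seed sample must belong to the discriminating set")

    @property
    def size(self) -> int:
        return len(self.discriminating_set)


@dataclass
class SearchParams:
    """Multistart search settings.

    num_seeds (n_s) random restarts; discriminating_size (s_d) samples per
    seed; alpha — minimum fraction of the *original* sample count a module
    must cover; min_genes — minimum |G| for a module to be reported
    (defaults to 1, i.e. no extra filtering, for the plain CGEM search).
    """

    num_seeds: int = 10
    discriminating_size: int = 7
    alpha: float = 0.05
    min_genes: int = 1
    rng_seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.num_seeds < 1:
            raise ValueError("num_seeds must be >= 1")
        if not (1 <= self.discriminating_size <= n_samples):
            raise ValueError("discriminating_size must be in [1, M]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.min_genes < 1:
            raise ValueError("min_genes must be >= 1")


@dataclass
class ConservedModule:
    """A conserved gene-state module: gene-state pairs G and samples C.

    ``genes[k]`` is conserved in state ``states[k]`` across every sample in
    ``samples``. ``msr`` is the Mean Squared Residue of the continuous
    values over genes × samples (infinity for an empty gene set, which by
    vacuous agreement matches all samples and is never selected).
    """

    genes: np.ndarray
    states: np.ndarray
    samples: np.ndarray
    msr: float = np.inf
    seed: Seed | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.genes.size != self.states.size:
            raise ValueError("one state per conserved gene required")

    @property
    def n_genes(self) -> int:
        return int(self.genes.size)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def size(self) -> int:
        """|G| × |C|, the row-column size of the bicluster."""
        return self.n_genes * self.n_samples

    def to_record(self, gene_ids: Sequence[str] | None = None,
                  sample_ids: Sequence[str] | None = None) -> dict:
        rec = {
            "genes": [gene_ids[g] if gene_ids else int(g) for g in self.genes],
            "states": [int(s) for s in self.states],
            "samples": [sample_ids[s] if sample_ids else int(s) for s in self.samples],
            "n_genes": self.n_genes,
            "n_samples": self.n_samples,
            "size": self.size,
            "msr": None if not np.isfinite(self.msr) else float(self.msr),
        }
        if self.seed is not None:
            rec["seed"] = {"seed_sample": int(self.seed.seed_sample),
                           "discriminating_set": sorted(self.seed.discriminating_set)}
        return rec


def build_module(disc: DiscretizedMatrix, seed: Seed,
                 values: ExpressionMatrix | np.ndarray | None = None,
                 sample_pool: np.ndarray | None = None) -> ConservedModule:
    """Induce the conserved module of a seed.

    G = {(g, state(g, c)) : state(g, d) = state(g, c) for all d in D};
    C = {samples in the pool agreeing with c on every pair in G}.
    If G is empty the agreement is vacuous and C is the whole pool. When
    ``values`` is given and G is nonempty, the module's MSR is computed on
    the continuous values; otherwise it is +inf.

    ``sample_pool`` restricts C (and must contain D) during iterative
    extraction; by default all samples are candidates.
    """
    S = disc.states
    m = S.shape[1]
    c = int(seed.seed_sample)
    D = np.fromiter(sorted(seed.discriminating_set), dtype=np.int64)
    if c < 0 or c >= m or D.min() < 0 or D.max() >= m:
        raise ValueError("seed indices outside sample range")
    pool = np.arange(m, dtype=np.int64) if sample_pool is None \
        else np.asarray(sample_pool, dtype=np.int64)
    agree = np.all(S[:, D] == S[:, c:c + 1], axis=1)
    genes = np.flatnonzero(agree)
    states = S[genes, c]
    if genes.size == 0:
        samples = pool.copy()
    else:
        match = np.all(S[np.ix_(genes, pool)] == states[:, None], axis=0)
        samples = pool[match]
    module = ConservedModule(genes, states, samples, seed=seed)
    if values is not None and genes.size > 0 and samples.size > 0:
        module.msr = msr(values, Bicluster(genes, samples))
    return module


def draw_seed(rng: np.random.Generator, n_samples: int, s_d: int,
              sample_pool: np.ndarray | None = None) -> Seed:
    """Uniform seed: c uniform in the pool, D uniform among size-s_d
    subsets of the pool containing c."""
    pool = np.arange(n_samples) if sample_pool is None else np.asarray(sample_pool)
    picks = rng.choice(pool, size=s_d, replace=False)
    return Seed(int(picks[0]), frozenset(int(p) for p in picks))


def enumerate_seeds(n_samples: int, s_d: int,
                    sample_pool: np.ndarray | None = None) -> Iterable[Seed]:
    """All (c, D) seeds in canonical order (c ascending, D lexicographic)."""
    pool = list(range(n_samples)) if sample_pool is None else [int(x) for x in sample_pool]
    for c in pool:
        rest = [x for x in pool if x != c]
        for combo in itertools.combinations(rest, s_d - 1):
            yield Seed(c, frozenset((c, *combo)))


def _passes_filters(module: ConservedModule, alpha: float, m_original: int,
                    min_genes: int) -> bool:
    if module.n_genes < max(1, min_genes):
        return False
    return module.n_samples >= alpha * m_original


def _better(a: ConservedModule, b: ConservedModule) -> bool:
    """Tie-break chain: larger |G|, then larger |C|, then lower msr,
    then first found (caller keeps the incumbent on full ties)."""
    if a.n_genes != b.n_genes:
        return a.n_genes > b.n_genes
    if a.n_samples != b.n_samples:
        return a.n_samples > b.n_samples
    return a.msr < b.msr


def find_largest_module(disc: DiscretizedMatrix,
                        values: ExpressionMatrix | np.ndarray | None,
                        params: SearchParams,
                        sample_pool: np.ndarray | None = None,
                        seeds: Iterable[Seed] | None = None,
                        rng: np.random.Generator | None = None,
                        m_original: int | None = None) -> ConservedModule | None:
    """Multistart search for the module with the most conserved genes.

    Draws ``params.num_seeds`` seeds uniformly at random (or consumes the
    explicit ``seeds`` iterable, e.g. for exhaustive enumeration), discards
    modules covering fewer than alpha × M samples (M is always the
    original sample count, ``m_original``), and returns the survivor
    maximizing |G| under the documented tie-break chain. Returns ``None``
    when every module is discarded.
    """
    params.validate(disc.n_samples if sample_pool is None else len(sample_pool))
    m_orig = disc.n_samples if m_original is None else int(m_original)
    if seeds is None:
        if rng is None:
            rng = np.random.default_rng(params.rng_seed)
        seeds = (draw_seed(rng, disc.n_samples, params.discriminating_size,
                           sample_pool) for _ in range(params.num_seeds))
    best: ConservedModule | None = None
    for seed in seeds:
        module = build_module(disc, seed, values, sample_pool)
        if not _passes_filters(module, params.alpha, m_orig, params.min_genes):
            continue
        if best is None or _better(module, best):
            best = module
    return best


def extract_biclusters(disc: DiscretizedMatrix,
                       values: ExpressionMatrix | np.ndarray | None,
                       params: SearchParams,
                       max_modules: int = 10) -> list[ConservedModule]:
    """Iterative CGEM: find the largest module, remove its matched samples,
    repeat on the remainder.

    Stops when fewer than alpha × M samples remain (α is always relative
    to the original sample count), when no module survives the filter, or
    after ``max_modules`` rounds. The overall "best" bicluster of the list
    is the one maximizing |G| × |C| (see :func:`best_module`).
    """
    if max_modules < 1:
        raise ValueError("max_modules must be >= 1")
    m = disc.n_samples
    rng = np.random.default_rng(params.rng_seed)
    pool = np.arange(m, dtype=np.int64)
    out: list[ConservedModule] = []
    while len(out) < max_modules and pool.size >= params.alpha * m and pool.size >= params.discriminating_size:
        module = find_largest_module(disc, values, params, sample_pool=pool,
                                     rng=rng, m_original=m)
        if module is None:
            break
        out.append(module)
        pool = np.setdiff1d(pool, module.samples)
    return out


def best_module(modules: Sequence[ConservedModule]) -> ConservedModule | None:
    """The module with the largest row-column size |G| × |C|."""
    if not modules:
        return None
    return max(modules, key=lambda mod: mod.size)
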