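"""Planted-module synthetic benchmark data.

Generates an expression matrix in which most cells are background — each
gene's discrete state drawn uniformly over q wide, well-separated state
intervals — and one block of (module_genes × module_samples) cells is a
planted conserved module: each planted gene holds a single fixed state
across all planted samples, with continuous values following an additive
row + column model plus Gaussian noise, so the block has near-zero Mean
Squared Residue and the planted truth coincides with the MSR optimum the
search targets. A matched driver-gene census (planted genes plus random
decoys) supports end-to-end enrichment testing.

Geometry of the continuous values (chosen once; see docs/methods.md):
state centers sit ``state_spacing`` apart (default 2.0), background values
jitter uniformly within ±0.9 of their center, and the planted block's
row/column offsets are uniform in ±0.15 — wide state intervals relative to
the block's noise, so moderate noise degrades recovery gradually instead
of collapsing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cgem import ConservedModule
from .matrix import ExpressionMatrix, write_expression_matrix

__all__ = [
    "PlantedModuleSpec",
    "PlantedModule",
    "GroundTruth",
    "generate",
    "recovery_score",
    "make_census",
    "write_fixture",
    "read_truth",
]

_BACKGROUND_JITTER = 0.45   # fraction of state_spacing
_BLOCK_OFFSET = 0.075       # fraction of state_spacing, for row and column each


@dataclass
class PlantedModuleSpec:
    """Generator settings: matrix dimensions, planted block size, number of
    discrete states q, additive Gaussian noise SD, background style
    (``uniform_states``: i.i.d. uniform states; ``shuffled``: exactly
    balanced state counts per gene, randomly permuted)."""

    num_genes_total: int = 200
    num_samples_total: int = 40
    module_genes: int = 20
    module_samples: int = 12
    num_states: int = 3
    noise_sd: float = 0.25
    state_spacing: float = 2.0
    background: str = "uniform_states"
    rng_seed: int = 0

    def validate(self) -> None:
        if self.num_states < 2:
            raise ValueError("num_states must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.module_genes > self.num_genes_total:
            raise ValueError("planted block has more genes than the matrix")
        if self.module_samples > self.num_samples_total:
            raise ValueError("planted block has more samples than the matrix")
        if self.background not in ("uniform_states", "shuffled"):
            raise ValueError(f"unknown background style {self.background!r}")


@dataclass
class PlantedModule:
    gene_indices: np.ndarray
    sample_indices: np.ndarray
    gene_states: np.ndarray  # the conserved state of each planted gene

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        self.gene_states = np.asarray(self.gene_states, dtype=np.int64)


@dataclass
class GroundTruth:
    """Planted module(s) plus the full generating state assignment."""

    modules: list[PlantedModule]
    states: np.ndarray = field(repr=False)
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def planted_gene_ids(self) -> set[str]:
        out: set[str] = set()
        for mod in self.modules:
            out |= {self.gene_ids[g] for g in mod.gene_indices}
        return out


def generate(spec: PlantedModuleSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Emit (matrix, truth), deterministic under ``spec.rng_seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n, m, q = spec.num_genes_total, spec.num_samples_total, spec.num_states
    sp = spec.state_spacing

    if spec.background == "uniform_states":
        states = rng.integers(0, q, size=(n, m))
    else:  # balanced counts per gene, shuffled
        base = np.resize(np.arange(q), m)
        states = np.stack([rng.permutation(base) for _ in range(n)])

    gene_idx = np.sort(rng.choice(n, size=spec.module_genes, replace=False))
    sample_idx = np.sort(rng.choice(m, size=spec.module_samples, replace=False))
    gene_states = rng.integers(0, q, size=spec.module_genes)
    states[np.ix_(gene_idx, sample_idx)] = gene_states[:, None]

    jitter = rng.uniform(-_BACKGROUND_JITTER * sp, _BACKGROUND_JITTER * sp, size=(n, m))
    values = states * sp + jitter
    # planted block: additive row + column model around the state centers
    row_off = rng.uniform(-_BLOCK_OFFSET * sp, _BLOCK_OFFSET * sp, size=spec.module_genes)
    col_off = rng.uniform(-_BLOCK_OFFSET * sp, _BLOCK_OFFSET * sp, size=spec.module_samples)
    values[np.ix_(gene_idx, sample_idx)] = (gene_states[:, None] * sp
                                            + row_off[:, None] + col_off[None, :])
    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, size=(n, m))

    width = len(str(n))
    gene_ids = [f"g{i:0{width}d}" for i in range(n)]
    sample_ids = [f"s{j:03d}" for j in range(m)]
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = GroundTruth([PlantedModule(gene_idx, sample_idx, gene_states)],
                        states, gene_ids, sample_ids)
    return matrix, truth


def _jaccard(found: np.ndarray, planted: np.ndarray) -> float:
    f, p = set(found.tolist()), set(planted.tolist())
    union = f | p
    if not union:
        return 1.0
    return len(f & p) / len(union)


def recovery_score(found: ConservedModule, truth: GroundTruth) -> tuple[float, float]:
    """(gene_jaccard, sample_jaccard) against the best-matching planted
    module (the one maximizing the summed Jaccard)."""
    best = (-1.0, (0.0, 0.0))
    for mod in truth.modules:
        gj = _jaccard(found.genes, mod.gene_indices)
        sj = _jaccard(found.samples, mod.sample_indices)
        if gj + sj > best[0]:
            best = (gj + sj, (gj, sj))
    return best[1]


def make_census(truth: GroundTruth, extra_decoys: int,
                rng: np.random.Generator) -> set[str]:
    """Planted gene ids plus ``extra_decoys`` random non-planted genes —
    a synthetic stand-in for a curated driver-gene census."""
    if extra_decoys < 0:
        raise ValueError("extra_decoys must be >= 0")
    planted = truth.planted_gene_ids
    others = sorted(set(truth.gene_ids) - planted)
    k = min(extra_decoys, len(others))
    decoys = set(rng.choice(others, size=k, replace=False).tolist()) if k else set()
    return planted | decoys


def write_fixture(spec: PlantedModuleSpec, out_dir: str | Path,
                  extra_decoys: int = 100) -> dict[str, Path]:
    """Write matrix TSV, truth JSON, and census text for a spec; returns
    the paths. These are exactly the formats the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = generate(spec)
    rng = np.random.default_rng(spec.rng_seed + 1)
    census = make_census(truth, extra_decoys, rng)
    paths = {
        "matrix": out / "matrix.tsv",
        "truth": out / "truth.json",
        "census": out / "census.txt",
    }
    write_expression_matrix(matrix, paths["matrix"])
    truth_doc = {
        "spec": asdict(spec),
        "modules": [
            {
                "gene_ids": [truth.gene_ids[g] for g in mod.gene_indices],
                "sample_ids": [truth.sample_ids[s] for s in mod.sample_indices],
                "gene_indices": mod.gene_indices.tolist(),
                "sample_indices": mod.sample_indices.tolist(),
                "gene_states": mod.gene_states.tolist(),
            }
            for mod in truth.modules
        ],
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2), encoding="utf-8")
    paths["census"].write_text(
        "# synthetic driver-gene census: planted genes + decoys\n"
        + "\n".join(sorted(census)) + "\n", encoding="utf-8")
    return paths


def read_truth(path: str | Path) -> dict:
    """Load a truth JSON written by :func:`write_fixture`."""
    return json.loads(Path(path).read_text(encoding="utf-8"))
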