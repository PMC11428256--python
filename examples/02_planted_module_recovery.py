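"""Recover a planted conserved module with the genetic-algorithm search.

Generates a 200-gene × 40-sample matrix containing one planted 20×12
conserved module (noise SD 0.25), runs CGEMGA, and compares the best
module against the planted truth. Jaccard 1.0 on both axes means the
search found exactly the planted genes and samples.
"""

from cgemga import GAParams
from cgemga.benchmark import run_recovery
from cgemga.synthetic import PlantedModuleSpec

spec = PlantedModuleSpec(noise_sd=0.25, rng_seed=11)
result = run_recovery(spec, GAParams(rng_seed=12))

mod = result.module
print(f"planted block: 20 genes × 12 samples")
print(f"found module:  {mod.n_genes} genes × {mod.n_samples} samples, "
      f"MSR {mod.msr:.4f}")
print(f"gene Jaccard:   {result.gene_jaccard:.3f}")
print(f"sample Jaccard: {result.sample_jaccard:.3f}")
print(f"fitness evaluations: {result.n_evaluations}")

trace = result.trace.best_fitness_per_generation
print(f"\nconvergence trace (best fitness per generation): "
      f"{[f'{x:.3g}' for x in trace[:8]]} ...")
print(f"final best reached at generation {result.trace.generation_of_convergence} "
      "(the search is designed to settle within a handful of generations)")
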