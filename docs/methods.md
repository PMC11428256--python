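# Methods

## The model

A gene expression study is a real-valued matrix `X` of `N` genes × `M`
samples (assumed already normalized and log-scaled). A *bicluster* is a
submatrix `B = (I, J)` — a gene subset and a sample subset — and its
coherence is measured by the Mean Squared Residue

    H(I, J) = (1 / |I||J|) Σ_{i∈I, j∈J} (a_ij − a_iJ − a_Ij + a_IJ)²

where `a_iJ`, `a_Ij`, `a_IJ` are the row, column, and grand means of the
submatrix. `H = 0` exactly when the submatrix is additive
(`a_ij = r_i + c_j`), which covers constant blocks and any single row or
column; lower is more coherent. MSR is always evaluated on the original
continuous values (accumulated in numpy row-major order, so a given input
reproduces its score bit-for-bit), never on discretized states.

A *conserved module* (xmotif-style) is defined through a per-gene
discretization of expression into `q` ordinal states. A seed is a sample
`c` plus a discriminating sample subset `D ∋ c` of size `s_d`. The seed
induces

* `G` = the gene–state pairs `(g, state(g, c))` for every gene whose state
  agrees across all of `D`, and
* `C` = every sample that agrees with `c` on all pairs in `G`.

`C ⊇ D` always; an empty `G` matches all samples vacuously and is never
reported. The baseline CGEM search draws seeds at random, keeps modules
covering at least a fraction α of the samples, returns the survivor with
the most conserved genes (ties: larger `|C|`, lower MSR, first found), and
extracts successive biclusters by removing matched samples and repeating;
α always refers to the original sample count, and the final "best" of an
extraction is the module maximizing `|G| × |C|`.

CGEMGA replaces random seeding with a genetic algorithm over seed
chromosomes `[c, d_1, …, d_{s_d−1}]` (duplicate-free sample indices),
evolved with size-`k` tournament selection, single-point crossover,
per-locus mutation (resampling among unused indices, followed by
duplicate repair), and elitism. Several restarts run independently; each
returns its best admissible module and the restarts' modules are reported
in ascending MSR order with `|G| × |C|` breaking ties.

## Fitness: why not raw MSR

Under i.i.d. noise with variance σ², the expected MSR of an `|I| × |J|`
block is `σ² (1 − 1/|I|)(1 − 1/|J|)`: it *grows with block size*, and a
single row or column scores exactly 0 by algebra. Minimizing raw MSR over
candidate modules therefore converges to degenerate sub-blocks, not to
the largest coherent module. The search handles this in two ways.

**Size-adjusted score.** Admissible modules compete on
`H / ((1 − 1/|I|)(1 − 1/|J|))` — the exact unbiasing divisor — so a
sub-block of a coherent module no longer wins merely by being smaller,
while any genuinely incoherent row or column still raises the score.
Module records always carry the raw MSR alongside.

**Admissibility floors with graded penalties.** A reported module must
have at least `min_genes` genes (default 10 — an expression module worth
reporting is a multi-gene signature) and cover at least α of the cohort
(GA default 0.25 — the scale of recurrent expression subgroups). The
floors also cap a second bias: the *empirical minimum* of a variance
estimate over adaptively chosen row/column subsets drifts low, and the
drift grows as the subset shrinks (relative spread ≈ `sqrt(2/df)` with
`df = (|I|−1)(|J|−1)`). Without the coverage floor the search measurably
prunes samples to flatter its own score. During evolution the floors are
graded, not hard: an undersized module scores
`H + deficit × H(whole matrix)` where `deficit` counts missing genes plus
missing samples. Hard walls would make nearly every random seed invisible
to selection and leave crossover/mutation nothing to climb; the graded
form keeps the landscape connected, which is precisely what lets a seed
two samples short of a conserved block evolve into it. Empty modules get
an infinite sentinel. The baseline CGEM search keeps the permissive
α = 0.05 and no gene floor: its max-`|G|` objective has no incentive to
shrink modules.

## Parameters

| parameter | default | meaning / why |
|---|---|---|
| `q` (`num_states`) | 3 | low / baseline / high expression; smallest q separating up- and down-regulation |
| discretization | `equal_width_trimmed` | per-gene equal-width intervals anchored on the 2%/98% quantiles. Quantile (equal-frequency) binning balances occupancy by construction, so it would cut straight through a conserved value cluster; plain min/max anchoring lets noise tails drag every cut inward (≈5% state flips at noise SD 0.25 on the benchmark). Both alternatives remain available |
| `s_d` | 7 | discriminating samples per seed; ~(1/q)^(s_d−1) controls how often a background gene joins G by chance (≈0.25 genes per seed at q=3, 200 genes) |
| α | 0.25 (GA), 0.05 (CGEM) | minimum sample coverage of a reported module; see above |
| `min_genes` | 10 (GA), 1 (CGEM) | minimum genes of a reported module; see above |
| population | 150 | sized so an initial population usually contains a seed sharing most of its samples with any α-worthy conserved block |
| tournament size | 8 | selection pressure high enough that such a seed's lineage dominates within a few generations |
| crossover / mutation | 0.8 / 0.2 | single-point crossover; per-locus resample among unused indices |
| elitism / patience / MAX | 1 / 10 / 100 | best seed always survives; a restart stops after 10 generations without improvement |
| restarts (`n_s`) | 10 | independent GA runs; the final module list pools their bests |

All exposed in `GAParams` / `SearchParams` and as CLI flags. The
population/selection defaults were chosen by measuring
convergence-generation distributions on the synthetic benchmark: the
method is designed to settle within a handful of generations, which the
defaults achieve (typically ≤5 generations to the final best).

## Enrichment evaluation

Found genes (the union across reported modules) are compared against a
driver-gene census inside the experiment's gene universe:
`a` = found ∧ census, `b` = found only, `c` = census only, `d` = neither.
Census genes absent from the universe are dropped first — the test should
only count genes the experiment could have found. The point probability
of a table under fixed margins is `m!n!r!s! / (a!b!c!d!N!)`, evaluated in
log-gamma space; the exact test sums point probabilities over the
admissible tables with `a′ ≥ a` (one-sided, the enrichment direction and
the default — association with a driver census is only meaningful in one
direction; two-sided, defined by point probabilities not exceeding the
observed within relative tolerance 1e-7, is available behind a flag).
Multi-run results are summarized as mean ± sample SD (n−1; a single run
reports SD 0) and formatted in scientific notation ("1.54 × 10^-4").

## The synthetic benchmark

`synthetic.generate` emits a background matrix with one planted conserved
block plus the ground truth. Geometry, chosen once:

* state centers sit `state_spacing = 2.0` apart; background cells draw a
  state uniformly (i.i.d., or exactly balanced per gene with
  `background="shuffled"`) and jitter uniformly within ±0.9 of the center
  — states are wide and well separated;
* the planted block fixes one state per planted gene across all planted
  samples and sets continuous values to the state center plus additive
  row and column offsets, each uniform in ±0.15 — so at zero noise the
  block's MSR is exactly 0 and the planted truth coincides with the
  optimum the search targets;
* Gaussian noise of SD `noise_sd` (default 0.25) is added to every cell.

With these proportions the within-state spread of background values
(variance ≈ 0.27) dominates the block's noise (0.0625 at the default SD),
so absorbing any background row or column into a module visibly raises
its score — the property that makes the planted module identifiable. The
default instance is 200 genes × 40 samples with a 20×12 block, q = 3:
large enough that chance conservation is realistic, small enough that a
full recovery study runs in minutes on one CPU. `make_census` builds a
synthetic driver census (planted genes + decoys) so the whole pipeline,
enrichment included, runs without external data.

What the generator does **not** emulate: real expression marginals,
gene–gene correlation outside the module, sample covariates, batch
effects, multiple overlapping modules, or the 12k-gene scale of real
cohorts (all dimensions are config knobs). Passing the benchmark shows
the search machinery is correct and calibrated on identifiable instances;
it does not certify recovery rates on real cohort data.

## Numerical choices and degenerate inputs

* Interval convention: left-closed/right-open, last interval closed; a
  value exactly at a cut point goes up. Duplicate cut points collapse, so
  low-diversity genes occupy fewer states and a constant gene is state 0.
* `equal_frequency` cut points are linear-interpolation quantiles at
  k/q; the assignment depends only on value ranks, so it is invariant
  under strictly increasing transforms of a gene's values.
* Missing or non-numeric cells, duplicate identifiers, and ragged rows
  are load-time errors (no imputation, no silent coercion); full-precision
  writes round-trip bit-exactly (numpy strtod on read).
* Fisher tails are summed in log space; an all-zero table returns 1.
* All randomness flows through `numpy.random.Generator`; restarts draw
  from `SeedSequence.spawn`, so a run is reproducible from its single
  seed and restart results are independent of execution order.
* 1×n / n×1 biclusters are legal for scoring (MSR 0); the search floors
  exclude them from reports.

## Known limitations

* One module per GA run-list entry: overlapping or hierarchical module
  structure is only addressed by the CGEM-style iterative extraction with
  sample removal.
* The min-MSR objective needs the admissibility floors to be well-posed;
  on data whose interesting modules are smaller than `min_genes` or rarer
  than α, those floors must be lowered by the user.
* Equal-width binning assumes per-gene value ranges are meaningful; data
  with heavy outliers beyond the 2% trim or strongly multimodal
  background may need a different `q` or method.
* The budget-matched CGEM comparison counts module evaluations, not wall
  time; the two searches do comparable work per evaluation, but the
  comparison is algorithmic, not a runtime benchmark.
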