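"""Discretize a small expression matrix and score a candidate bicluster.

Builds a 6-gene × 8-sample matrix in which genes g0-g2 follow an additive
row + column pattern on samples s0-s3, discretizes each gene into three
expression states, and scores two candidate biclusters with the Mean
Squared Residue (MSR). The coherent block scores ~0 (perfectly additive);
a random block scores far higher — lower MSR means a more coherent module.
"""

import numpy as np

from cgemga import Bicluster, ExpressionMatrix, discretize, msr

rng = np.random.default_rng(0)
values = rng.uniform(0, 6, size=(6, 8))
row_effect = np.array([0.0, 1.0, 2.0])
col_effect = np.array([0.0, 0.5, 1.0, 1.5])
values[:3, :4] = 3.0 + row_effect[:, None] + col_effect[None, :]

matrix = ExpressionMatrix([f"g{i}" for i in range(6)],
                          [f"s{j}" for j in range(8)], values)

disc = discretize(matrix, num_states=3)
print("expression states (one row per gene, 0=low .. 2=high):")
for gid, row in zip(disc.gene_ids, disc.states):
    print(f"  {gid}: {row.tolist()}")

coherent = Bicluster([0, 1, 2], [0, 1, 2, 3])
random_block = Bicluster([3, 4, 5], [4, 5, 6, 7])
print(f"\nMSR of the additive block g0-g2 × s0-s3: {msr(matrix, coherent):.3g}")
print(f"MSR of a background block g3-g5 × s4-s7: {msr(matrix, random_block):.3g}")
print("\nThe additive block scores ~0: its cells are row + column effects, "
      "the coherence pattern the module search minimizes toward.")
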