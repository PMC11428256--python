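"""Mean Squared Residue (MSR) scoring of submatrices.

For a submatrix indexed by rows I and columns J of a matrix A, with row
means a_iJ, column means a_Ij, and grand mean a_IJ, the MSR is

    H(I, J) = (1 / |I||J|) * sum_{i in I, j in J}
              (a_ij - a_iJ - a_Ij + a_IJ)^2

MSR is 0 exactly when the submatrix follows an additive model
a_ij = r_i + c_j (which includes constant submatrices and any 1×n or n×1
submatrix); lower MSR means a more coherent bicluster. It is the fitness
criterion of the genetic-algorithm module search, always evaluated on the
original continuous expression values, never on discretized states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Bicluster", "SubmatrixMeans", "submatrix_means", "msr"]


@dataclass
class Bicluster:
    """A gene index set I and sample index set J, with an optional score."""

    gene_index_set: np.ndarray
    sample_index_set: np.ndarray
    msr: float | None = None

    def __post_init__(self) -> None:
        self.gene_index_set = np.asarray(self.gene_index_set, dtype=np.int64)
        self.sample_index_set = np.asarray(self.sample_index_set, dtype=np.int64)
        for name, idx in (("gene", self.gene_index_set),
                          ("sample", self.sample_index_set)):
            if idx.size == 0:
                raise ValueError(f"empty {name} index set")
            if np.unique(idx).size != idx.size:
                raise ValueError(f"duplicate indices in {name} index set")
            if idx.min() < 0:
                raise ValueError(f"negative {name} index")


@dataclass
class SubmatrixMeans:
    row_means: np.ndarray   # a_iJ, one per i in I
    column_means: np.ndarray  # a_Ij, one per j in J
    grand_mean: float       # a_IJ


def _extract(matrix, bicluster: Bicluster) -> np.ndarray:
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, dtype=np.float64)
    rows, cols = bicluster.gene_index_set, bicluster.sample_index_set
    if rows.max() >= values.shape[0] or cols.max() >= values.shape[1]:
        raise ValueError("bicluster index outside matrix bounds")
    return values[np.ix_(rows, cols)]


def submatrix_means(matrix, bicluster: Bicluster) -> SubmatrixMeans:
    """Row, column, and grand means of the bicluster's submatrix."""
    sub = _extract(matrix, bicluster)
    return SubmatrixMeans(
        row_means=sub.mean(axis=1),
        column_means=sub.mean(axis=0),
        grand_mean=float(sub.mean()),
    )


def msr(matrix, bicluster: Bicluster) -> float:
    """Mean Squared Residue H(I, J) of the bicluster's submatrix.

    Accepts an :class:`~cgemga.matrix.ExpressionMatrix` or a plain 2-D
    array. Accumulation is numpy row-major, so identical input reproduces
    the score bit-for-bit.
    """
    sub = _extract(matrix, bicluster)
    residues = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
    return float(np.mean(residues ** 2))
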