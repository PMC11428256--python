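"""Expression-matrix container, I/O, and per-gene discretization.

The search operates on two synchronized views of the same data: the
continuous expression values (used for Mean Squared Residue scoring) and a
per-gene discretization into a small number of ordinal "expression states"
(used to define conservation: a gene is conserved across a sample subset
when its state is identical in every one of those samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DiscretizedMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "discretize",
    "write_states",
]


@dataclass
class ExpressionMatrix:
    """A genes × samples grid of real-valued (pre-normalized) expression.

    Parameters
    ----------
    gene_ids
        Row identifiers, unique, one per gene (length N).
    sample_ids
        Column identifiers, unique, one per sample/condition (length M).
    values
        float64 array of shape (N, M); no missing values allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("empty matrix: need at least one gene and one sample")
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene id: {dup[0]!r}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample id: {dup[0]!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class DiscretizedMatrix:
    """Integer expression state per cell plus the per-gene interval cuts.

    ``states[g, s] == k`` iff gene g's value in sample s falls in the gene's
    k-th interval. Intervals are left-closed/right-open with the last
    interval closed; a value exactly at a cut point belongs to the upper
    interval. Duplicate cut points are collapsed, so low-diversity genes may
    occupy fewer than ``num_states`` effective states (a constant gene is
    always state 0).
    """

    num_states: int
    boundaries: list[np.ndarray]
    states: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 2:
            raise ValueError("states must be 2-D")
        if len(self.boundaries) != self.states.shape[0]:
            raise ValueError("one boundary array required per gene")
        if self.states.min() < 0 or self.states.max() > self.num_states - 1:
            raise ValueError("state outside [0, num_states-1]")

    @property
    def n_genes(self) -> int:
        return self.states.shape[0]

    @property
    def n_samples(self) -> int:
        return self.states.shape[1]


def _duplicates(ids: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Load a genes × samples matrix from TSV/CSV.

    First row is the header ``id<sep>sample_1<sep>...``; each further row is
    a gene id followed by M numeric cells. The delimiter is inferred from
    the extension (``.csv`` → comma, anything else → tab) unless given.

    Raises a distinct :class:`ValueError` (or :class:`FileNotFoundError`)
    for: missing file, empty file / header-only file, duplicate gene or
    sample ids, ragged rows, and non-numeric cells. There is no silent
    coercion and no imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    try:
        # na_filter off: keep cells verbatim so "NA" etc. surface as the
        # non-numeric errors they are, and short rows appear as "" cells
        raw = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str,
                          skip_blank_lines=True, na_filter=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty matrix: {path} has no content") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"ragged rows in {path}: {exc}") from None
    if raw.shape[0] == 0:
        raise ValueError(f"empty matrix: {path} contains only a header row")
    # header-duplicate detection: pandas mangles duplicate column names, so
    # re-read the raw header line for the authoritative sample ids
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split(sep)
    sample_ids = header[1:]
    if len(sample_ids) != raw.shape[1]:
        raise ValueError(f"ragged rows in {path}: header/body width mismatch")
    gene_ids = [str(g) for g in raw.index]
    cells = raw.to_numpy(dtype=str)
    if (cells == "").any():
        i = int(np.argwhere(cells == "")[0][0])
        raise ValueError(f"ragged rows in {path}: short row for gene {gene_ids[i]!r}")
    try:
        # numpy's string→float conversion is exact (strtod), so full-precision
        # writes round-trip bit-for-bit
        values = cells.astype(np.float64)
    except ValueError:
        for (i, j), cell in np.ndenumerate(cells):
            try:
                float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
        raise
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            delimiter: str | None = None) -> None:
    """Write TSV/CSV at full float precision (round-trips bit-exactly)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = matrix.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep=sep)


def discretize(matrix: ExpressionMatrix, num_states: int = 3,
               method: str = "equal_width_trimmed",
               trim: float = 0.02) -> DiscretizedMatrix:
    """Partition each gene's values independently into ordinal states.

    ``equal_width`` splits a gene's [min, max] range into ``num_states``
    equal intervals; ``equal_width_trimmed`` (the default) does the same
    but anchors the range on the ``trim``/(1 − ``trim``) quantiles, so a
    handful of extreme values cannot drag the cut points off the bulk of
    the distribution (min and max are order statistics with zero breakdown
    — under noise they shift every cut inward by a tail-sized amount);
    ``equal_frequency`` places cut points at the k/q quantiles
    (k = 1..q−1). A width-based method is the default because a conserved
    module concentrates many samples of a gene into one value cluster;
    quantile cuts are forced through such clusters (they balance occupancy
    by construction) and would split the conserved state.

    Duplicate or degenerate cut points are collapsed, so genes with little
    diversity get fewer effective states; a constant gene is state 0
    everywhere.
    """
    if num_states < 1:
        raise ValueError("num_states must be >= 1")
    if method not in ("equal_frequency", "equal_width", "equal_width_trimmed"):
        raise ValueError(f"unknown discretization method {method!r}")
    if method == "equal_frequency" and num_states > matrix.n_samples:
        raise ValueError(
            f"num_states={num_states} exceeds sample count {matrix.n_samples} "
            "for equal_frequency binning"
        )
    if not (0 <= trim < 0.5):
        raise ValueError("trim must lie in [0, 0.5)")
    q = num_states
    n, m = matrix.values.shape
    states = np.empty((n, m), dtype=np.int64)
    boundaries: list[np.ndarray] = []
    fracs = np.arange(1, q) / q
    for i in range(n):
        row = matrix.values[i]
        if method == "equal_width_trimmed":
            lo, hi = np.quantile(row, [trim, 1.0 - trim])
        else:
            lo, hi = row.min(), row.max()
        if q == 1 or lo == hi:
            cuts = np.empty(0, dtype=np.float64)
        elif method == "equal_frequency":
            cuts = np.quantile(row, fracs)
        else:
            cuts = lo + (hi - lo) * fracs
        cuts = np.unique(cuts)
        cuts = cuts[cuts > row.min()]  # a cut at/below the minimum would leave state 0 empty
        states[i] = np.searchsorted(cuts, row, side="right")
        boundaries.append(cuts)
    return DiscretizedMatrix(q, boundaries, states,
                             list(matrix.gene_ids), list(matrix.sample_ids))


def write_states(disc: DiscretizedMatrix, path: str | Path,
                 delimiter: str | None = None) -> None:
    """Serialize the integer state grid to TSV/CSV for inspection."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(disc.states, index=disc.gene_ids or None,
                      columns=disc.sample_ids or None)
    df.index.name = "id"
    df.to_csv(path, sep=sep)
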