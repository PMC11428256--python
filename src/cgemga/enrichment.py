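"""Driver-gene enrichment of discovered modules via Fisher's exact test.

The genes found by a biclustering run are compared against a curated
driver-gene census (e.g. a cancer gene census) in a 2×2 contingency table:

    a = found ∧ in census       b = found ∧ not in census
    c = not found ∧ in census   d = neither

with margins m = a+c, n = b+d, r = a+b, s = c+d and total N. The point
probability of a table under fixed margins is the hypergeometric term

    p = m! n! r! s! / (a! b! c! d! N!)

computed in log-factorial space; the exact test sums point probabilities
over the admissible tables (a' ≥ a for the one-sided enrichment tail, or
all tables at most as probable as the observed one for the two-sided
test). A threshold of p < 0.05 flags significant driver-gene enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "RunSummary",
    "point_probability",
    "fisher_exact",
    "build_contingency",
    "summarize_runs",
    "format_scientific",
    "read_census",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 counts; margins and total are derived, hence always consistent."""

    a: int  # found and in census
    b: int  # found, not in census
    c: int  # not found, in census
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def m(self) -> int:
        return self.a + self.c

    @property
    def n(self) -> int:
        return self.b + self.d

    @property
    def r(self) -> int:
        return self.a + self.b

    @property
    def s(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _log_point_probability(a: int, b: int, c: int, d: int) -> float:
    num = gammaln(a + c + 1) + gammaln(b + d + 1) + gammaln(a + b + 1) + gammaln(c + d + 1)
    den = (gammaln(a + 1) + gammaln(b + 1) + gammaln(c + 1) + gammaln(d + 1)
           + gammaln(a + b + c + d + 1))
    return float(num - den)


def point_probability(table: ContingencyTable) -> float:
    """Hypergeometric probability of the table given its margins.

    m!·n!·r!·s! / (a!·b!·c!·d!·N!), evaluated via log-gamma to avoid
    overflow; an all-zero table returns 1 by the 0! convention.
    """
    return math.exp(_log_point_probability(table.a, table.b, table.c, table.d))


def _support(table: ContingencyTable) -> range:
    """Admissible a' values with the observed margins held fixed."""
    lo = max(0, table.r - table.n)
    hi = min(table.r, table.m)
    return range(lo, hi + 1)


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Exact test over all 2×2 tables sharing the observed margins.

    ``greater`` (default; the enrichment direction) sums point
    probabilities of tables with a' ≥ a. ``two_sided`` sums tables whose
    point probability does not exceed the observed one (relative tolerance
    1e-7). Returns a p-value in (0, 1].
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m, r, total = table.m, table.r, table.total
    support = _support(table)
    ap = np.arange(support.start, support.stop)
    bp, cp = r - ap, m - ap
    dp = total - m - r + ap
    num = gammaln(m + 1) + gammaln(total - m + 1) + gammaln(r + 1) \
        + gammaln(total - r + 1)
    logs = num - (gammaln(ap + 1) + gammaln(bp + 1) + gammaln(cp + 1)
                  + gammaln(dp + 1) + gammaln(total + 1))
    if alternative == "greater":
        tail = logs[ap >= table.a]
    else:
        obs = logs[ap == table.a][0]
        tail = logs[logs <= obs + math.log1p(1e-7)]
    p = float(np.exp(tail).sum())
    return min(p, 1.0)


def build_contingency(found_genes: Iterable[str], census: Iterable[str],
                      universe: Iterable[str]) -> ContingencyTable:
    """Contingency table of found genes vs census within a gene universe.

    Census genes absent from the universe are dropped first (the test can
    only count genes the experiment could have found); found genes must be
    a subset of the universe.
    """
    found, census, universe = set(found_genes), set(census), set(universe)
    stray = found - universe
    if stray:
        raise ValueError("found genes absent from universe: "
                         + ", ".join(sorted(stray)[:10]))
    census &= universe
    a = len(found & census)
    b = len(found - census)
    c = len(census - found)
    d = len(universe - (found | census))
    return ContingencyTable(a, b, c, d)


def format_scientific(x: float, digits: int = 2) -> str:
    """Render a number the way result tables print it: ``1.54 × 10^-4``."""
    if x == 0:
        return "0"
    exp = math.floor(math.log10(abs(x)))
    mant = x / 10 ** exp
    mant = round(mant, digits)
    if abs(mant) >= 10:  # rounding pushed the mantissa over a decade
        mant /= 10
        exp += 1
    return f"{mant:.{digits}f} × 10^{exp}"


@dataclass
class RunSummary:
    """Mean ± sample SD of p-values and MSR values over independent runs."""

    pvalues: list[float]
    msrs: list[float]
    mean_p: float
    sd_p: float
    mean_msr: float
    sd_msr: float
    significance_threshold: float = 0.05

    @property
    def significant(self) -> bool:
        return self.mean_p < self.significance_threshold

    def format_p(self) -> str:
        return f"{format_scientific(self.mean_p)} ± {format_scientific(self.sd_p)}"

    def format_msr(self) -> str:
        return f"{format_scientific(self.mean_msr)} ± {format_scientific(self.sd_msr)}"


def _mean_sd(xs: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(xs, dtype=np.float64)
    mean = float(arr.mean())
    sd = 0.0 if arr.size < 2 else float(arr.std(ddof=1))
    return mean, sd


def summarize_runs(pvalues: Sequence[float], msrs: Sequence[float],
                   significance_threshold: float = 0.05) -> RunSummary:
    """Mean and sample standard deviation (n−1 denominator; a single run
    has SD 0) of per-run p-values and MSR values."""
    if len(pvalues) == 0 or len(msrs) == 0:
        raise ValueError("need at least one run to summarize")
    if len(pvalues) != len(msrs):
        raise ValueError("pvalues and msrs must have equal length")
    mean_p, sd_p = _mean_sd(pvalues)
    mean_msr, sd_msr = _mean_sd(msrs)
    return RunSummary(list(pvalues), list(msrs), mean_p, sd_p, mean_msr, sd_msr,
                      significance_threshold)


def read_census(path: str | Path) -> set[str]:
    """Plain-text census: one gene symbol per line, '#' comments allowed."""
    path = Path(path)
    genes: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes
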