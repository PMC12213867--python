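"""Cross-disease gene-set overlap: contingency tables, odds ratio, Fisher test.

Two disease gene sets drawn from a common universe are compared through the
2x2 contingency table (in both / A only / B only / neither).  Enrichment is
summarized by the sample cross-product odds ratio n11*n00 / (n10*n01) and
Fisher's exact test.  The universe size is always an explicit input — the
size of the neither-cell drives the odds ratio, so it must never be inferred
from the union of the two sets.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Collection, Iterable

from scipy import stats

__all__ = [
    "Sidedness",
    "ContingencyTable",
    "OverlapResult",
    "contingency_from_sets",
    "contingency_from_sizes",
    "odds_ratio",
    "fisher_exact_p",
    "overlap_report",
]


class Sidedness(str, enum.Enum):
    TWO_SIDED = "two_sided"
    GREATER = "greater"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 membership table of two gene sets in a universe."""

    n11: int  # in both sets
    n10: int  # in A only
    n01: int  # in B only
    n00: int  # in neither

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def universe_n(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_rows(self) -> list[list[int]]:
        return [[self.n11, self.n10], [self.n01, self.n00]]


@dataclass(frozen=True)
class OverlapResult:
    """Venn summary and enrichment statistics for two gene sets."""

    size_a: int
    size_b: int
    overlap: int
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    a_only: tuple[str, ...] = ()
    b_only: tuple[str, ...] = ()
    shared: tuple[str, ...] = ()


def contingency_from_sets(
    set_a: Collection[str], set_b: Collection[str], universe: Collection[str]
) -> ContingencyTable:
    """Build the 2x2 table by set algebra; both sets must lie in the universe."""
    a, b, u = set(set_a), set(set_b), set(universe)
    offenders = sorted((a | b) - u)
    if offenders:
        shown = ", ".join(offenders[:10])
        more = "" if len(offenders) <= 10 else f" (+{len(offenders) - 10} more)"
        raise ValueError(f"genes outside the universe: {shown}{more}")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - n11 - n10 - n01
    return ContingencyTable(n11, n10, n01, n00)


def contingency_from_sizes(
    size_a: int, size_b: int, overlap: int, universe_n: int
) -> ContingencyTable:
    """Build the 2x2 table from published set sizes rather than explicit sets."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either set size")
    n11 = overlap
    n10 = size_a - overlap
    n01 = size_b - overlap
    n00 = universe_n - n11 - n10 - n01
    return ContingencyTable(n11, n10, n01, n00)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample (unconditional) cross-product odds ratio.

    A zero off-diagonal product with a positive diagonal product gives +inf;
    the doubly degenerate 0/0 case is reported as 1 (no evidence either way).
    This is the cross-product ratio, not the conditional maximum-likelihood
    estimate some exact-test routines report.
    """
    num = table.n11 * table.n00
    den = table.n10 * table.n01
    if den == 0:
        return math.inf if num > 0 else 1.0
    return num / den


def fisher_exact_p(
    table: ContingencyTable, sidedness: Sidedness = Sidedness.TWO_SIDED
) -> float:
    """Fisher's exact hypergeometric test probability for the 2x2 table.

    ``two_sided`` sums all tables with point probability <= the observed
    one; ``greater`` is the upper (enrichment) tail.
    """
    sidedness = Sidedness(sidedness)
    alternative = "two-sided" if sidedness is Sidedness.TWO_SIDED else "greater"
    return float(stats.fisher_exact(table.as_rows(), alternative=alternative)[1])


def overlap_report(
    set_a: Collection[str],
    set_b: Collection[str],
    universe: Collection[str],
    sidedness: Sidedness = Sidedness.TWO_SIDED,
) -> OverlapResult:
    """Full overlap summary: Venn counts, gene lists, odds ratio, exact p."""
    a, b = set(set_a), set(set_b)
    table = contingency_from_sets(a, b, universe)
    return OverlapResult(
        size_a=len(a),
        size_b=len(b),
        overlap=table.n11,
        table=table,
        odds_ratio=odds_ratio(table),
        p_value=fisher_exact_p(table, sidedness),
        a_only=tuple(sorted(a - b)),
        b_only=tuple(sorted(b - a)),
        shared=tuple(sorted(a & b)),
    )
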