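"""Adjusted binomial scoring of literature-mined gene-disease relationships.

A gene-disease pair is supported by a set of mentions, each positive,
negative, or unknown.  The adjusted binomial method asks whether the
*dominant* polarity class (the strictly most frequent of the three) occurs
more often than a null proportion ``p0`` would predict, after inflating the
observation count to allow for literature the mining stage did not cover.

With raw counts (n_p, n_n, n_0) summing to n and uncovered-sample fraction
``alpha_frac`` (default 1, i.e. assume as many uncovered studies as covered
ones), the effective total is N = n + round(alpha_frac * n) and the dominant
count is inflated by the same factor.  The one-tailed p-value is the binomial
survival tail P(X >= n_dom_adj) for X ~ Binomial(N, p0).  The null proportion
p0 = 0.34 is just above 1/3, the smallest share at which one class of three
can dominate, so the test asks whether dominance is more than marginal.

Screening a disease runs the test for every gene with at least one mention
and applies Benjamini-Hochberg FDR control across exactly that family of
genes; the operative significance screen is q <= 0.01.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evidence_io import Direction, EvidenceRecord, Polarity, PolarityCounts, tabulate_counts

logger = logging.getLogger(__name__)

__all__ = [
    "AbmaParams",
    "AbmaResult",
    "total_observations",
    "abma_test",
    "bh_fdr",
    "screen_disease",
    "results_to_frame",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class AbmaParams:
    """Tuning parameters of the adjusted binomial screen.

    alpha_frac
        Ratio of uncovered to covered studies; 1 doubles every count.
    p0
        Null dominance proportion; 0.34 is the smallest share at which one
        of three polarity classes can strictly dominate.
    alpha_sig
        Nominal per-test significance level, retained for reporting.
    q_threshold
        Benjamini-Hochberg FDR cutoff used as the operative screen.
    """

    alpha_frac: float = 1.0
    p0: float = 0.34
    alpha_sig: float = 0.05
    q_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.alpha_frac < 0:
            raise ValueError(f"alpha_frac must be >= 0, got {self.alpha_frac}")
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must be in (0, 1), got {self.p0}")
        if not 0 < self.q_threshold <= 1:
            raise ValueError(f"q_threshold must be in (0, 1], got {self.q_threshold}")


@dataclass
class AbmaResult:
    """Outcome of the adjusted binomial test for one gene-disease pair."""

    gene: str
    disease: str
    dominant_polarity: Optional[Polarity]
    n_pos: int
    n_neg: int
    n_unk: int
    n_raw: int
    n_uncovered: int
    n_total: int
    n_adj: int
    nd_adj: int
    prop_obs: float
    p_value: float
    q_value: Optional[float] = None
    significant: bool = False
    direction: Optional[Direction] = None  # set by direction-partitioned screens

    @property
    def dominant_label(self) -> str:
        return self.dominant_polarity.value if self.dominant_polarity else "none"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def total_observations(
    counts: PolarityCounts, alpha_frac: float = 1.0
) -> tuple[int, int]:
    """Effective sample size after inflating for uncovered literature.

    Returns ``(n_uncovered, n_total)`` where n_uncovered =
    round(alpha_frac * (n_p + n_n + n_0)), rounded half-up to an integer, and
    n_total adds it to the raw total.  With alpha_frac = 1 this doubles the
    raw count exactly.
    """
    if alpha_frac < 0:
        raise ValueError(f"alpha_frac must be >= 0, got {alpha_frac}")
    n_raw = counts.total
    n_uncovered = _round_half_up(alpha_frac * n_raw)
    return n_uncovered, n_raw + n_uncovered


def _dominant(counts: PolarityCounts) -> Optional[tuple[Polarity, int]]:
    """The strictly largest polarity class, or None on tie / no evidence."""
    trio = [
        (counts.n_pos, Polarity.POSITIVE),
        (counts.n_neg, Polarity.NEGATIVE),
        (counts.n_unk, Polarity.UNKNOWN),
    ]
    best = max(n for n, _ in trio)
    if best == 0 or sum(1 for n, _ in trio if n == best) > 1:
        return None
    pol = next(p for n, p in trio if n == best)
    return pol, best


def abma_test(counts: PolarityCounts, params: AbmaParams = AbmaParams()) -> AbmaResult:
    """Adjusted binomial test of polarity dominance for one pair.

    Degenerate evidence (no mentions, or a tie for the most frequent class)
    yields dominant_polarity None and p = 1 rather than an exception: such a
    pair simply cannot be called.  Otherwise the dominant count and the total
    are both inflated by the uncovered-sample factor and the p-value is the
    upper binomial tail at the adjusted dominant count.
    """
    n_uncovered, n_total = total_observations(counts, params.alpha_frac)
    base = dict(
        gene="",
        disease="",
        n_pos=counts.n_pos,
        n_neg=counts.n_neg,
        n_unk=counts.n_unk,
        n_raw=counts.total,
        n_uncovered=n_uncovered,
        n_total=n_total,
    )
    dom = _dominant(counts)
    if dom is None:
        return AbmaResult(
            dominant_polarity=None, n_adj=n_total, nd_adj=0,
            prop_obs=float("nan"), p_value=1.0, **base,
        )
    pol, n_dom = dom
    n_adj = n_total
    nd_adj = n_dom + _round_half_up(params.alpha_frac * n_dom)
    prop_obs = nd_adj / n_adj
    if prop_obs <= 1 / 3:  # unreachable under strict dominance; kept as a guard
        return AbmaResult(
            dominant_polarity=None, n_adj=n_adj, nd_adj=nd_adj,
            prop_obs=prop_obs, p_value=1.0, **base,
        )
    p_value = float(stats.binom.sf(nd_adj - 1, n_adj, params.p0))
    return AbmaResult(
        dominant_polarity=pol, n_adj=n_adj, nd_adj=nd_adj,
        prop_obs=prop_obs, p_value=p_value, **base,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Order-preserving with the input positions and capped at 1.  Raises for
    any p outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_disease(
    records: Iterable[EvidenceRecord],
    disease: str,
    params: AbmaParams = AbmaParams(),
    direction: Direction = Direction.ANY,
) -> list[AbmaResult]:
    """Run the adjusted binomial screen over every gene mentioned with a disease.

    The BH family is exactly the set of genes with >= 1 matching mention
    (after the direction filter): untested hypotheses are not part of the
    family.  Results are ordered by gene symbol.  A disease absent from the
    records yields an empty list with a logged warning.
    """
    direction = Direction(direction)
    records = list(records)
    genes = sorted({r.gene for r in records if r.disease == disease})
    if not genes:
        logger.warning("no evidence records for disease %r", disease)
        return []
    results: list[AbmaResult] = []
    for gene in genes:
        counts = tabulate_counts(records, gene, disease, direction)
        if counts.total == 0:  # all mentions filtered out by direction
            continue
        res = abma_test(counts, params)
        res.gene = gene
        res.disease = disease
        if direction is not Direction.ANY:
            res.direction = direction
        results.append(res)
    if not results:
        logger.warning(
            "no evidence for disease %r in direction %s", disease, direction.value
        )
        return []
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.significant = bool(qv <= params.q_threshold)
    return results


def results_to_frame(results: Iterable[AbmaResult]) -> pd.DataFrame:
    """Flatten screen results into the canonical result table."""
    cols = [
        "gene", "disease", "n_pos", "n_neg", "n_unk", "dominant",
        "n_adj", "nd_adj", "prop_obs", "p_value", "q_value", "significant",
    ]
    rows = [
        {
            "gene": r.gene,
            "disease": r.disease,
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "n_unk": r.n_unk,
            "dominant": r.dominant_label,
            "n_adj": r.n_adj,
            "nd_adj": r.nd_adj,
            "prop_obs": r.prop_obs,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m for m >= 1 tests."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m
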