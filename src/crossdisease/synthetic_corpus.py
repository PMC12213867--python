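"""Synthetic evidence corpora with planted ground truth.

The generator emulates the output of a literature-mining stage for two
diseases over a fixed gene universe: a minority of genes is truly associated
with each disease, joint association between the two diseases is enriched to
a planted odds ratio, truly associated pairs receive several mentions whose
polarities concentrate on a planted dominant class, and null pairs receive
sporadic mentions with a near-uniform polarity mixture.  Every planted label
is recorded in a truth table so downstream stages can be scored for recall
and false-discovery rate.

Joint association is sampled from the 2x2 cell probabilities implied by the
two marginal prevalences and the planted odds ratio (the Plackett one-root
quadratic).  Mention counts are Poisson: zero-truncated for associated pairs
(a truly associated pair always leaves at least one trace in the literature)
and plain Poisson for null pairs.  The count parameter is the rate of the
underlying Poisson, so the realized mean for associated pairs is slightly
above ``mean_refs_true`` when the rate is small.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .evidence_io import EvidenceRecord, Polarity

__all__ = [
    "SyntheticParams",
    "joint_cell_probability",
    "generate_corpus",
]

# Planted dominant class for a true association: most literature signals are
# signed; a fifth of associations are reported without a usable sign.
_DOMINANT_CLASS_PROBS = {
    Polarity.POSITIVE: 0.4,
    Polarity.NEGATIVE: 0.4,
    Polarity.UNKNOWN: 0.2,
}


@dataclass(frozen=True)
class SyntheticParams:
    """Ground-truth design of a synthetic evidence corpus.

    Defaults describe the standard simulation condition used throughout the
    test-bench: a 2,000-gene universe, 10% prevalence per disease, joint
    association enriched to an odds ratio of 7.5 (the scale of overlap seen
    between an autoimmune disease and a cancer in mined corpora), eight
    expected mentions per true pair of which 90% carry the planted dominant
    polarity, and a sparse near-uniform background.  The background rate of
    0.25 expected mentions per null pair makes roughly a fifth of null genes
    show up in the corpus at all, matching the scale of mined corpora in
    which only ~20-30% of a whole-genome universe co-occurs with a given
    disease in the literature.
    """

    n_genes: int = 2000
    diseases: tuple[str, str] = ("RA", "HNC")
    prevalence_a: float = 0.1
    prevalence_b: float = 0.1
    overlap_odds_ratio: float = 7.5
    mean_refs_true: float = 8.0
    mean_refs_null: float = 0.25
    dominant_prob_true: float = 0.9
    polarity_null: tuple[float, float, float] = (0.34, 0.33, 0.33)
    direction_gene_to_disease_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence_a <= 1 or not 0 <= self.prevalence_b <= 1:
            raise ValueError("prevalences must lie in [0, 1]")
        if self.overlap_odds_ratio <= 0:
            raise ValueError("overlap_odds_ratio must be > 0")
        if not 0.34 < self.dominant_prob_true <= 1:
            raise ValueError(
                "dominant_prob_true must exceed 0.34, the null dominance "
                f"proportion, for the planted signal to be detectable; got "
                f"{self.dominant_prob_true}"
            )
        if not math.isclose(sum(self.polarity_null), 1.0, abs_tol=1e-9):
            raise ValueError("polarity_null must sum to 1")
        if self.mean_refs_true < 0 or self.mean_refs_null < 0:
            raise ValueError("mention-count means must be >= 0")
        if not 0 <= self.direction_gene_to_disease_prob <= 1:
            raise ValueError("direction_gene_to_disease_prob must lie in [0, 1]")
        if self.diseases[0] == self.diseases[1]:
            raise ValueError("the two disease identifiers must differ")


def joint_cell_probability(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(associated with both) for given marginals and odds ratio.

    Solves theta = p11*p00 / (p10*p01) for p11 with p10 = p_a - p11,
    p01 = p_b - p11, p00 = 1 - p_a - p_b + p11; the admissible root of the
    quadratic (theta - 1) p11^2 - [1 + (p_a + p_b)(theta - 1)] p11
    + theta p_a p_b = 0.
    """
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if math.isclose(odds_ratio, 1.0):
        return p_a * p_b
    t = odds_ratio - 1.0
    b = 1.0 + (p_a + p_b) * t
    disc = b * b - 4.0 * t * odds_ratio * p_a * p_b
    p11 = (b - math.sqrt(disc)) / (2.0 * t)
    # numerical guard: the root must lie in the Frechet bounds
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    return min(max(p11, lo), hi)


def _zero_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Sample Poisson(lam) conditioned on being >= 1, by inverse CDF."""
    if lam <= 0:
        return np.ones(size, dtype=np.int64)
    u = rng.uniform(math.exp(-lam), 1.0, size=size)
    # invert the (untruncated) Poisson CDF on [P(0), 1)
    from scipy import stats

    return stats.poisson.ppf(u, lam).astype(np.int64)


def _sample_polarities(
    rng: np.random.Generator, k: int, probs: dict[Polarity, float]
) -> list[Polarity]:
    pols = list(probs.keys())
    idx = rng.choice(len(pols), size=k, p=[probs[p] for p in pols])
    return [pols[i] for i in idx]


def generate_corpus(
    params: SyntheticParams,
) -> tuple[list[EvidenceRecord], pd.DataFrame]:
    """Generate an evidence corpus and its ground-truth table.

    Returns ``(records, truth)``.  The truth table has one row per gene with
    columns ``gene``, ``associated_a``, ``associated_b``,
    ``planted_polarity_a``, ``planted_polarity_b`` (the planted dominant
    class, or ``none`` for null pairs).  Deterministic given
    ``params.seed``; every truly associated pair emits at least one mention.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i:05d}" for i in range(1, params.n_genes + 1)]
    disease_a, disease_b = params.diseases

    p11 = joint_cell_probability(
        params.prevalence_a, params.prevalence_b, params.overlap_odds_ratio
    )
    p10 = params.prevalence_a - p11
    p01 = params.prevalence_b - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = rng.choice(4, size=params.n_genes, p=[p11, p10, p01, p00])
    assoc_a = np.isin(cells, (0, 1))
    assoc_b = np.isin(cells, (0, 2))

    dom_classes = list(_DOMINANT_CLASS_PROBS)
    dom_probs = [_DOMINANT_CLASS_PROBS[p] for p in dom_classes]
    null_probs = dict(zip(
        (Polarity.POSITIVE, Polarity.NEGATIVE, Polarity.UNKNOWN), params.polarity_null
    ))

    records: list[EvidenceRecord] = []
    truth_rows: list[dict] = []
    ref_counter = 0

    def emit(gene: str, disease: str, associated: bool) -> Optional[Polarity]:
        nonlocal ref_counter
        if associated:
            k = int(_zero_truncated_poisson(rng, params.mean_refs_true, 1)[0])
            planted = dom_classes[rng.choice(len(dom_classes), p=dom_probs)]
            rest = [p for p in dom_classes if p is not planted]
            probs = {planted: params.dominant_prob_true}
            for p in rest:
                probs[p] = (1.0 - params.dominant_prob_true) / 2.0
        else:
            k = int(rng.poisson(params.mean_refs_null))
            planted = None
            probs = null_probs
        if k == 0:
            return planted
        polarities = _sample_polarities(rng, k, probs)
        gene_first = rng.uniform(size=k) < params.direction_gene_to_disease_prob
        for pol, g_first in zip(polarities, gene_first):
            ref_counter += 1
            subject, obj = (gene, disease) if g_first else (disease, gene)
            records.append(
                EvidenceRecord(
                    gene=gene,
                    disease=disease,
                    polarity=pol,
                    subject=subject,
                    object=obj,
                    reference_id=f"SYN{ref_counter:08d}",
                    source="synthetic",
                )
            )
        return planted

    for gene, a, b in zip(genes, assoc_a, assoc_b):
        planted_a = emit(gene, disease_a, bool(a))
        planted_b = emit(gene, disease_b, bool(b))
        truth_rows.append(
            {
                "gene": gene,
                "associated_a": bool(a),
                "associated_b": bool(b),
                "planted_polarity_a": planted_a.value if planted_a else "none",
                "planted_polarity_b": planted_b.value if planted_b else "none",
            }
        )

    truth = pd.DataFrame(truth_rows)
    return records, truth
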