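"""Directed, signed disease->gene->disease path construction.

A path connects two diseases through one intermediate gene using two
independently significant directional relationships: disease A acts on the
gene and the gene acts on disease B (or the mirror orientation).  Convergent
(A -> gene <- B) and divergent (A <- gene -> B) patterns are never paths — the
arrows do not compose into a regulatory chain.  Each path carries a net sign:
the product of the two edge polarities, with an unknown polarity on either
edge absorbing the product to unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .abma import AbmaParams, AbmaResult, screen_disease
from .evidence_io import Direction, EvidenceRecord, Polarity

__all__ = [
    "RelationshipEdge",
    "PathTriplet",
    "net_sign",
    "significant_directed_edges",
    "screen_directional",
    "find_disease_gene_disease_paths",
    "pathway_report",
]


@dataclass(frozen=True)
class RelationshipEdge:
    """A significant directional relationship between two entities."""

    subject: str
    object: str
    polarity: Polarity
    n_refs: int
    q_value: float

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError("subject and object must differ")
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"q_value must lie in [0, 1], got {self.q_value}")


def net_sign(a: Polarity, b: Polarity) -> Polarity:
    """Sign composition: + * + = + , + * - = - , - * - = + ; unknown absorbs."""
    if Polarity.UNKNOWN in (a, b):
        return Polarity.UNKNOWN
    return Polarity.POSITIVE if a == b else Polarity.NEGATIVE


@dataclass(frozen=True)
class PathTriplet:
    """One disease_from -> gene -> disease_to regulatory path."""

    disease_from: str
    gene: str
    disease_to: str
    edge_in: RelationshipEdge  # disease_from -> gene
    edge_out: RelationshipEdge  # gene -> disease_to

    def __post_init__(self) -> None:
        if not (
            self.edge_in.subject == self.disease_from
            and self.edge_in.object == self.gene
            and self.edge_out.subject == self.gene
            and self.edge_out.object == self.disease_to
        ):
            raise ValueError("edges do not chain disease_from -> gene -> disease_to")

    @property
    def net_sign(self) -> Polarity:
        return net_sign(self.edge_in.polarity, self.edge_out.polarity)


def significant_directed_edges(
    results: Iterable[AbmaResult], q_threshold: float = 0.01
) -> list[RelationshipEdge]:
    """Keep directional screen results significant at q <= threshold as edges.

    ``results`` must come from direction-filtered screens (one evidence
    partition per orientation), so each result maps to one directed edge:
    the subject is whichever side acted in that partition.  Results with no
    dominant polarity or with q above the threshold are dropped; the edge
    polarity is the dominant polarity of the directional evidence.
    """
    edges: list[RelationshipEdge] = []
    for r in results:
        if r.q_value is None or r.q_value > q_threshold:
            continue
        if r.dominant_polarity is None:
            continue
        if r.direction == Direction.GENE_TO_DISEASE:
            subject, obj = r.gene, r.disease
        elif r.direction == Direction.DISEASE_TO_GENE:
            subject, obj = r.disease, r.gene
        else:
            raise ValueError(
                f"result for ({r.gene}, {r.disease}) lacks a direction; "
                "run the screen with an explicit direction filter"
            )
        edges.append(
            RelationshipEdge(
                subject=subject,
                object=obj,
                polarity=r.dominant_polarity,
                n_refs=r.n_raw,
                q_value=r.q_value,
            )
        )
    return edges


def screen_directional(
    records: Iterable[EvidenceRecord],
    disease: str,
    params: AbmaParams = AbmaParams(),
) -> list[AbmaResult]:
    """Run the adjusted binomial screen separately per evidence orientation.

    Gene->disease and disease->gene mentions form separate evidence
    partitions with separate BH families, so a gene may be significant in
    one orientation only.  Each returned result is annotated with the
    ``direction`` it was screened under.
    """
    records = list(records)
    out: list[AbmaResult] = []
    for direction in (Direction.GENE_TO_DISEASE, Direction.DISEASE_TO_GENE):
        for r in screen_disease(records, disease, params, direction):
            r.direction = direction
            out.append(r)
    return out


def find_disease_gene_disease_paths(
    edges: Iterable[RelationshipEdge], disease_a: str, disease_b: str
) -> list[PathTriplet]:
    """All A -> gene -> B and B -> gene -> A paths among significant edges.

    Returns triplets sorted by (disease_from, gene).  A gene mediating both
    orientations yields both triplets.
    """
    if disease_a == disease_b:
        raise ValueError("the two diseases must differ")
    edges = list(edges)
    diseases = {disease_a, disease_b}
    # disease -> gene edges keyed by (disease, gene); gene -> disease likewise
    from_disease = {
        (e.subject, e.object): e for e in edges if e.subject in diseases
    }
    to_disease = {
        (e.subject, e.object): e for e in edges if e.object in diseases
    }
    triplets: list[PathTriplet] = []
    for (d_from, gene), e_in in from_disease.items():
        d_to = disease_b if d_from == disease_a else disease_a
        e_out = to_disease.get((gene, d_to))
        if e_out is not None:
            triplets.append(
                PathTriplet(
                    disease_from=d_from, gene=gene, disease_to=d_to,
                    edge_in=e_in, edge_out=e_out,
                )
            )
    triplets.sort(key=lambda t: (t.disease_from, t.gene))
    return triplets


def pathway_report(
    triplets: Sequence[PathTriplet],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate paths and their signed edges for export or plotting.

    Returns ``(paths, signed_edges)``: one row per triplet with both edges'
    polarities, support counts and q-values; and a de-duplicated signed edge
    list (source, target, polarity) suitable for network drawing, where the
    polarity string stands in for an edge color (positive / negative /
    unknown).
    """
    path_cols = [
        "disease_from", "gene", "disease_to", "net_sign",
        "in_polarity", "in_n_refs", "in_q_value",
        "out_polarity", "out_n_refs", "out_q_value",
    ]
    rows = [
        {
            "disease_from": t.disease_from,
            "gene": t.gene,
            "disease_to": t.disease_to,
            "net_sign": t.net_sign.value,
            "in_polarity": t.edge_in.polarity.value,
            "in_n_refs": t.edge_in.n_refs,
            "in_q_value": t.edge_in.q_value,
            "out_polarity": t.edge_out.polarity.value,
            "out_n_refs": t.edge_out.n_refs,
            "out_q_value": t.edge_out.q_value,
        }
        for t in triplets
    ]
    paths = pd.DataFrame(rows, columns=path_cols)
    seen: dict[tuple[str, str], str] = {}
    for t in triplets:
        for e in (t.edge_in, t.edge_out):
            seen.setdefault((e.subject, e.object), e.polarity.value)
    signed_edges = pd.DataFrame(
        [{"source": s, "target": o, "polarity": p} for (s, o), p in sorted(seen.items())],
        columns=["source", "target", "polarity"],
    )
    return paths, signed_edges
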