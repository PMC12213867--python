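import pytest

from crossdisease.evidence_io import EvidenceRecord, Polarity
from crossdisease.pathway_builder import RelationshipEdge


def record(gene="TLR2", disease="RA", polarity=Polarity.POSITIVE,
           gene_is_subject=True, reference_id="PMID1", source="pubmed"):
    subject, obj = (gene, disease) if gene_is_subject else (disease, gene)
    return EvidenceRecord(
        gene=gene, disease=disease, polarity=polarity,
        subject=subject, object=obj, reference_id=reference_id, source=source,
    )


@pytest.fixture
def small_records():
    """Three well-formed mentions for one gene-disease pair."""
    return [
        record(reference_id="PMID1"),
        record(reference_id="PMID2"),
        record(polarity=Polarity.NEGATIVE, reference_id="PMID3"),
    ]


@pytest.fixture
def loop_edges():
    """The signed, significant directional relationships of the two-disease
    feedback loop: one disease drives a transcription factor that promotes
    the other, which in turn regulates four genes feeding back positively."""
    P, N, U = Polarity.POSITIVE, Polarity.NEGATIVE, Polarity.UNKNOWN
    return [
        RelationshipEdge("HNC", "RELA", P, 4, 0.0032),
        RelationshipEdge("RELA", "RA", P, 16, 2.93e-12),
        RelationshipEdge("RA", "CDC42", N, 8, 6.77e-4),
        RelationshipEdge("RA", "CTSK", N, 15, 5.99e-4),
        RelationshipEdge("RA", "CXCL11", P, 10, 0.0011),
        RelationshipEdge("RA", "CYP2C19", U, 14, 0.0017),
        RelationshipEdge("CDC42", "HNC", P, 5, 7.74e-4),
        RelationshipEdge("CTSK", "HNC", P, 4, 0.0032),
        RelationshipEdge("CXCL11", "HNC", P, 4, 0.0032),
        RelationshipEdge("CYP2C19", "HNC", P, 4, 0.0032),
    ]
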