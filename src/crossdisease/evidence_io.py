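"""Evidence-table data model and I/O.

The unit of evidence is a *mention*: one literature-extracted statement that a
gene and a disease are related, carrying a polarity (positive / negative /
unknown), a direction (subject acts on object), a citation key, and a free
source tag.  Evidence tables are UTF-8 tab-separated files with a header row
naming the canonical columns; gene lists are plain text, one symbol per line.

Gene symbols are compared case-sensitively after stripping surrounding
whitespace — the gene-universe list is the authority on symbol spelling.
"""

from __future__ import annotations

import csv
import enum
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Polarity",
    "Direction",
    "EvidenceRecord",
    "PolarityCounts",
    "SchemaError",
    "EvidenceParseError",
    "EVIDENCE_COLUMNS",
    "read_evidence_table",
    "write_evidence_table",
    "tabulate_counts",
    "read_gene_list",
    "write_gene_list",
    "write_results",
]

EVIDENCE_COLUMNS = (
    "gene",
    "disease",
    "polarity",
    "subject",
    "object",
    "reference_id",
    "source",
)


class Polarity(str, enum.Enum):
    """Sign of an extracted relationship mention.

    ``positive`` covers predicates such as promotes / activates / induces /
    upregulates; ``negative`` covers inhibits / suppresses / downregulates;
    ``unknown`` is an inconclusive or unsigned statement.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "Polarity":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise EvidenceParseError(
                f"unrecognized polarity {token!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None


class Direction(str, enum.Enum):
    """Orientation filter for tabulating mentions of a gene-disease pair."""

    ANY = "any"
    GENE_TO_DISEASE = "gene_to_disease"
    DISEASE_TO_GENE = "disease_to_gene"


class SchemaError(ValueError):
    """An evidence table is missing a required column."""


class EvidenceParseError(ValueError):
    """A row of an evidence table could not be parsed."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One extracted relationship mention.

    ``subject`` and ``object`` must be ``gene`` and ``disease`` in one of the
    two orders: the direction of the statement is subject -> object (the
    subject is the upstream regulator).
    """

    gene: str
    disease: str
    polarity: Polarity
    subject: str
    object: str
    reference_id: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.reference_id:
            raise ValueError("reference_id must be non-empty")
        pair = (self.subject, self.object)
        if pair not in ((self.gene, self.disease), (self.disease, self.gene)):
            raise ValueError(
                f"(subject, object) = {pair!r} must be the (gene, disease) "
                f"pair ({self.gene!r}, {self.disease!r}) in either order"
            )

    @property
    def gene_is_subject(self) -> bool:
        return self.subject == self.gene


@dataclass(frozen=True)
class PolarityCounts:
    """Per-pair tallies of mention polarities (n_p, n_n, n_0)."""

    n_pos: int = 0
    n_neg: int = 0
    n_unk: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pos", "n_neg", "n_unk"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg + self.n_unk


def read_evidence_table(path: Union[str, Path]) -> list[EvidenceRecord]:
    """Read a tab-separated evidence table into records, preserving row order.

    The first line must be a header containing every canonical column
    (extra columns are ignored).  Polarity tokens are parsed
    case-insensitively.  Raises :class:`SchemaError` for a missing column and
    :class:`EvidenceParseError` (with the 1-based line number) for a bad row.
    """
    path = Path(path)
    records: list[EvidenceRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in EVIDENCE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {missing}; header was {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    EvidenceRecord(
                        gene=(row["gene"] or "").strip(),
                        disease=(row["disease"] or "").strip(),
                        polarity=Polarity.parse(row["polarity"] or ""),
                        subject=(row["subject"] or "").strip(),
                        object=(row["object"] or "").strip(),
                        reference_id=(row["reference_id"] or "").strip(),
                        source=(row["source"] or "").strip(),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise EvidenceParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_evidence_table(
    path: Union[str, Path], records: Iterable[EvidenceRecord]
) -> None:
    """Write records as the canonical TSV dialect (header always present)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.gene, r.disease, r.polarity.value, r.subject, r.object,
                 r.reference_id, r.source]
            )


def tabulate_counts(
    records: Iterable[EvidenceRecord],
    gene: str,
    disease: str,
    direction: Direction = Direction.ANY,
    dedupe_references: bool = False,
) -> PolarityCounts:
    """Tally mention polarities for one (gene, disease) pair.

    Each table row counts once.  With ``dedupe_references`` set, duplicate
    (gene, disease, reference_id, polarity) rows collapse to one — off by
    default, since the mined tables give no guarantee that one citation
    appears only once across sources.

    ``direction`` restricts to mentions oriented gene->disease or
    disease->gene; ``ANY`` pools both orientations.
    """
    direction = Direction(direction)
    n = {Polarity.POSITIVE: 0, Polarity.NEGATIVE: 0, Polarity.UNKNOWN: 0}
    seen: set[tuple[str, Polarity]] = set()
    for r in records:
        if r.gene != gene or r.disease != disease:
            continue
        if direction is Direction.GENE_TO_DISEASE and not r.gene_is_subject:
            continue
        if direction is Direction.DISEASE_TO_GENE and r.gene_is_subject:
            continue
        if dedupe_references:
            key = (r.reference_id, r.polarity)
            if key in seen:
                continue
            seen.add(key)
        n[r.polarity] += 1
    return PolarityCounts(
        n_pos=n[Polarity.POSITIVE], n_neg=n[Polarity.NEGATIVE], n_unk=n[Polarity.UNKNOWN]
    )


def read_gene_list(path: Union[str, Path]) -> list[str]:
    """Read a one-symbol-per-line gene list, preserving first-seen order.

    Symbols are stripped of surrounding whitespace; blank lines are skipped;
    duplicates are dropped with a logged warning.
    """
    path = Path(path)
    seen: set[str] = set()
    genes: list[str] = []
    n_dup = 0
    for line in path.read_text(encoding="utf-8").splitlines():
        symbol = line.strip()
        if not symbol:
            continue
        if symbol in seen:
            n_dup += 1
            continue
        seen.add(symbol)
        genes.append(symbol)
    if n_dup:
        logger.warning("%s: dropped %d duplicate gene symbol(s)", path, n_dup)
    return genes


def write_gene_list(path: Union[str, Path], genes: Iterable[str]) -> None:
    Path(path).write_text(
        "".join(f"{g}\n" for g in genes), encoding="utf-8"
    )


def write_results(
    path: Union[str, Path],
    rows: Union[pd.DataFrame, Sequence[dict]],
) -> None:
    """Write a result table as TSV, or JSON if the path ends in ``.json``.

    An empty input still produces a valid file (header-only TSV / empty JSON
    list).  Round-trip stable: reading the TSV back with pandas reproduces
    the data region.
    """
    path = Path(path)
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if path.suffix == ".json":
        path.write_text(
            json.dumps(rows.to_dict(orient="records"), indent=2, default=str) + "\n",
            encoding="utf-8",
        )
    else:
        rows.to_csv(path, sep="\t", index=False)
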