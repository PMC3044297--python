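"""GAF 2.x annotation I/O and grouping.

An annotation associates one gene product (keyed by source database and
object id — no cross-database identifier unification is attempted) with one
GO term, under one of the 18 GO evidence codes; a record whose evidence field
is empty carries the first-class code ``NA`` (not available).  Records whose
qualifier includes ``NOT`` are preserved through I/O but are excluded from
inconsistency detection and enrichment counting, since a negated annotation
does not imply annotation to the term's ancestors.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from typing import IO

from .ontology import GO_ID_RE

logger = logging.getLogger("goqc")

#: The 18 GO evidence codes plus the NA placeholder for unlabelled records.
EVIDENCE_CODES = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA", "NR",
        "NA",
    }
)

GAF_COLUMNS = 17


class GafFormatError(ValueError):
    """Malformed GAF line (column count, GO id, evidence code, taxon)."""


GeneKey = tuple[str, str]


@dataclass(frozen=True)
class AnnotationRecord:
    db: str
    db_object_id: str
    go_id: str
    db_object_symbol: str = ""
    qualifier: tuple[str, ...] = ()
    evidence_code: str = "NA"
    taxon_id: int = 1
    assigned_by: str = ""
    date: str = ""

    @property
    def gene_key(self) -> GeneKey:
        return (self.db, self.db_object_id)

    @property
    def is_negated(self) -> bool:
        return "NOT" in self.qualifier

    def with_go_id(self, go_id: str) -> "AnnotationRecord":
        return replace(self, go_id=go_id)


@dataclass
class AnnotationSet:
    """Ordered, stably iterable collection of annotation records."""

    records: list[AnnotationRecord] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def effective(self) -> list[AnnotationRecord]:
        """Records that participate in detection: NOT-qualified ones excluded."""
        return [r for r in self.records if not r.is_negated]


def _parse_taxon(fieldval: str, lineno: int) -> int:
    # multi-taxon interaction fields keep the first taxon only
    first = fieldval.split("|", 1)[0].strip()
    if first.startswith("taxon:"):
        first = first[len("taxon:"):]
    try:
        taxid = int(first)
    except ValueError:
        raise GafFormatError(f"line {lineno}: bad taxon field {fieldval!r}") from None
    if taxid <= 0:
        raise GafFormatError(f"line {lineno}: non-positive taxon {taxid}")
    return taxid


def read_gaf(stream: str | IO[str], source_label: str = "") -> AnnotationSet:
    """Read GAF 2.0/2.1/2.2 tab-delimited text.

    Exact duplicate records are dropped with a logged count; a missing
    evidence column becomes ``NA``; multi-taxon fields keep the first taxon.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[AnnotationRecord] = []
    seen: set[AnnotationRecord] = set()
    n_dup = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) != GAF_COLUMNS:
            raise GafFormatError(
                f"line {lineno}: expected {GAF_COLUMNS} columns, got {len(cols)}"
            )
        go_id = cols[4].strip()
        if not GO_ID_RE.match(go_id):
            raise GafFormatError(f"line {lineno}: malformed GO id {go_id!r}")
        evidence = cols[6].strip() or "NA"
        if evidence not in EVIDENCE_CODES:
            raise GafFormatError(
                f"line {lineno}: unknown evidence code {evidence!r}"
            )
        qualifier = tuple(q for q in cols[3].split("|") if q)
        record = AnnotationRecord(
            db=cols[0].strip(),
            db_object_id=cols[1].strip(),
            db_object_symbol=cols[2].strip(),
            qualifier=qualifier,
            go_id=go_id,
            evidence_code=evidence,
            taxon_id=_parse_taxon(cols[12], lineno),
            assigned_by=cols[14].strip(),
            date=cols[13].strip(),
        )
        if record in seen:
            n_dup += 1
            continue
        seen.add(record)
        records.append(record)
    if n_dup:
        logger.info("read_gaf: dropped %d exact duplicate records", n_dup)
    return AnnotationSet(records=records, source_label=source_label)


def write_gaf(annotations: AnnotationSet, stream: IO[str]) -> None:
    """Write GAF 2.2; ``read_gaf(write_gaf(x))`` reproduces every carried field."""
    stream.write("!gaf-version: 2.2\n")
    for r in annotations.records:
        cols = [""] * GAF_COLUMNS
        cols[0] = r.db
        cols[1] = r.db_object_id
        cols[2] = r.db_object_symbol
        cols[3] = "|".join(r.qualifier)
        cols[4] = r.go_id
        cols[6] = r.evidence_code
        cols[11] = "protein"
        cols[12] = f"taxon:{r.taxon_id}"
        cols[13] = r.date
        cols[14] = r.assigned_by
        stream.write("\t".join(cols) + "\n")


def group_by_gene_product(
    annotations: AnnotationSet,
) -> dict[GeneKey, list[AnnotationRecord]]:
    """Partition records by (db, db_object_id); order within groups is stable."""
    groups: dict[GeneKey, list[AnnotationRecord]] = {}
    for record in annotations.records:
        groups.setdefault(record.gene_key, []).append(record)
    return groups
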