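"""Detection and correction of the three semantic inconsistency classes.

Three formal rules over a gene product's annotations:

* **Redundant annotation** — the same gene product is annotated to a term and
  to one of that term's proper ancestors.  Under the true-path rule the
  ancestor annotation carries no extra information *when the evidence codes
  match*; when they differ (e.g. an experiment supports the parent while a
  computational method predicts the child) both annotations are legitimately
  retained, so pairs are reported with a ``same_evidence`` flag.
* **Biological-domain-inconsistent annotation** — a eukaryote-only term
  (e.g. nucleus) annotated to a prokaryotic gene product, or a
  prokaryote-only term (e.g. unidirectional conjugation) annotated to a
  eukaryotic one.  Gene products whose superkingdom is neither (viruses,
  unclassified) never flag.
* **Taxonomy-inconsistent annotation** — an annotation violating a term's
  only_in / never_in NCBI-taxon restriction (e.g. Golgi apparatus, restricted
  to Eukaryota, annotated to an E. coli gene product).

Correction is removal-based: flagged records are dropped (redundant pairs
drop the ancestor side), never remapped to invented replacement terms.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .annotations import AnnotationRecord, AnnotationSet, GeneKey
from .ontology import ANCESTRY_RELATIONS, OntologyGraph, ancestors, resolve_id
from .taxonomy import TaxonomyTree, is_descendant, superkingdom_of

logger = logging.getLogger("goqc")

KINDS = ("redundant", "domain", "taxon")


@dataclass(frozen=True)
class RedundantPair:
    gene_key: GeneKey
    ancestor_annotation: AnnotationRecord
    descendant_annotation: AnnotationRecord
    same_evidence: bool


@dataclass(frozen=True)
class Flag:
    """One flagged annotation with its inconsistency kind and a detail note."""

    record: AnnotationRecord
    kind: str  # one of KINDS
    detail: str = ""


@dataclass
class DomainTermLists:
    eukaryote_only: set[str] = field(default_factory=set)
    prokaryote_only: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.eukaryote_only & self.prokaryote_only
        if overlap:
            raise ValueError(
                f"terms in both domain lists: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class TaxonRestriction:
    go_id: str
    mode: str  # only_in | never_in
    taxon_id: int

    def __post_init__(self) -> None:
        if self.mode not in ("only_in", "never_in"):
            raise ValueError(f"bad restriction mode {self.mode!r}")


@dataclass
class LevelCounts:
    """The three-level counts of the summary tables."""

    gene_products: int = 0
    annotations: int = 0
    terms: int = 0


@dataclass
class InconsistencyReport:
    flagged: list[Flag]
    #: summary[source_label][kind] -> LevelCounts; kinds include
    #: "redundant_same_evidence" and "total" in addition to KINDS.
    summary: dict[str, dict[str, LevelCounts]]
    totals: dict[str, LevelCounts]

    def to_frame(self) -> pd.DataFrame:
        """Summary as a tidy table, one row per (database, kind)."""
        rows = []
        for label, kinds in sorted(self.summary.items()):
            for kind, c in kinds.items():
                rows.append((label, kind, c.gene_products, c.annotations, c.terms))
        for kind, c in self.totals.items():
            rows.append(("TOTAL", kind, c.gene_products, c.annotations, c.terms))
        return pd.DataFrame(
            rows,
            columns=["database", "kind", "gene_products", "annotations", "terms"],
        )


# -- list / restriction file I/O -----------------------------------------


def read_domain_lists(
    eukaryote_stream: str | IO[str], prokaryote_stream: str | IO[str]
) -> DomainTermLists:
    """Read the two one-accession-per-line lists; '#' lines are comments."""
    return DomainTermLists(
        eukaryote_only=_read_accessions(eukaryote_stream),
        prokaryote_only=_read_accessions(prokaryote_stream),
    )


def _read_accessions(stream: str | IO[str]) -> set[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = set()
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            out.add(line.split("\t")[0])
    return out


def read_restrictions(stream: str | IO[str]) -> list[TaxonRestriction]:
    """Read the restriction TSV: go_id, mode, taxon_id."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        go_id, mode, taxon = line.split("\t")
        out.append(TaxonRestriction(go_id, mode, int(taxon)))
    return out


# -- detection ------------------------------------------------------------


def _resolved_term(
    graph: OntologyGraph, record: AnnotationRecord, skip_log: list | None
) -> str | None:
    res = resolve_id(graph, record.go_id)
    if res.status == "primary":
        return record.go_id
    if res.status == "merged":
        return res.canonical
    if skip_log is not None:
        skip_log.append((record, f"unresolvable term ({res.status})"))
    logger.debug("skipping %s: term %s is %s", record.gene_key, record.go_id, res.status)
    return None


def detect_redundant(
    graph: OntologyGraph,
    annotations: AnnotationSet,
    relations: frozenset[str] = ANCESTRY_RELATIONS,
    skip_log: list | None = None,
) -> list[RedundantPair]:
    """All (ancestor-annotation, descendant-annotation) pairs per gene product.

    Merged accessions are resolved to their canonical id before the ancestry
    test; obsolete/unknown accessions are skipped and logged.  Proper ancestry
    only: a term annotated twice is a duplicate, not a redundancy.  Ancestry
    never crosses namespaces, so neither do pairs.
    """
    pairs: list[RedundantPair] = []
    groups: dict[GeneKey, list[AnnotationRecord]] = {}
    for record in annotations.effective():
        groups.setdefault(record.gene_key, []).append(record)
    anc_cache: dict[str, set[str]] = {}
    for gene_key, records in groups.items():
        resolved = [
            (rec, term)
            for rec in records
            if (term := _resolved_term(graph, rec, skip_log)) is not None
        ]
        for desc_rec, desc_term in resolved:
            if desc_term not in anc_cache:
                anc_cache[desc_term] = ancestors(graph, desc_term, relations)
            desc_anc = anc_cache[desc_term]
            for anc_rec, anc_term in resolved:
                if anc_rec is desc_rec:
                    continue
                if anc_term in desc_anc:
                    pairs.append(
                        RedundantPair(
                            gene_key=gene_key,
                            ancestor_annotation=anc_rec,
                            descendant_annotation=desc_rec,
                            same_evidence=(
                                anc_rec.evidence_code == desc_rec.evidence_code
                            ),
                        )
                    )
    return pairs


def detect_domain_inconsistent(
    lists: DomainTermLists,
    tree: TaxonomyTree,
    annotations: AnnotationSet,
    skip_log: list | None = None,
) -> list[Flag]:
    """Flag eukaryote-only terms on prokaryotes and prokaryote-only terms on
    eukaryotes; taxa outside both superkingdom classes never flag."""
    flags: list[Flag] = []
    for record in annotations.effective():
        if record.taxon_id not in tree:
            if skip_log is not None:
                skip_log.append((record, "unknown taxon"))
            continue
        kingdom = superkingdom_of(tree, record.taxon_id)
        if record.go_id in lists.eukaryote_only and kingdom in ("Bacteria", "Archaea"):
            flags.append(
                Flag(record, "domain", f"eukaryote-only term on {kingdom} taxon")
            )
        elif record.go_id in lists.prokaryote_only and kingdom == "Eukaryota":
            flags.append(
                Flag(record, "domain", "prokaryote-only term on Eukaryota taxon")
            )
    return flags


def detect_taxon_inconsistent(
    restrictions: Sequence[TaxonRestriction],
    tree: TaxonomyTree,
    annotations: AnnotationSet,
    graph: OntologyGraph | None = None,
    inherit: bool = False,
    skip_log: list | None = None,
) -> list[Flag]:
    """Flag annotations violating only_in / never_in taxon restrictions.

    By default a restriction applies to the annotated term itself; with
    ``inherit=True`` (requires ``graph``) restrictions on any ancestor of the
    term also apply, mirroring descent of restrictions along the hierarchy.
    """
    if inherit and graph is None:
        raise ValueError("inherit=True requires the ontology graph")
    by_term: dict[str, list[TaxonRestriction]] = {}
    for restriction in restrictions:
        if restriction.taxon_id not in tree:
            raise ValueError(
                f"restriction taxon {restriction.taxon_id} not in taxonomy"
            )
        by_term.setdefault(restriction.go_id, []).append(restriction)
    flags: list[Flag] = []
    for record in annotations.effective():
        if record.taxon_id not in tree:
            if skip_log is not None:
                skip_log.append((record, "unknown taxon"))
            continue
        terms = {record.go_id}
        if inherit and record.go_id in graph:
            terms |= ancestors(graph, record.go_id)
        for term in terms:
            for restriction in by_term.get(term, ()):
                desc = is_descendant(tree, record.taxon_id, restriction.taxon_id)
                if (restriction.mode == "only_in" and not desc) or (
                    restriction.mode == "never_in" and desc
                ):
                    flags.append(
                        Flag(
                            record,
                            "taxon",
                            f"{restriction.mode} taxon:{restriction.taxon_id} "
                            f"violated on {term}",
                        )
                    )
                    break
            else:
                continue
            break
    return flags


# -- correction -----------------------------------------------------------

REDUNDANCY_POLICIES = ("drop_ancestor_same_evidence", "drop_ancestor_all")


def correct_redundant(
    pairs: Sequence[RedundantPair],
    annotations: AnnotationSet,
    policy: str = "drop_ancestor_same_evidence",
) -> tuple[AnnotationSet, list[tuple[AnnotationRecord, str]]]:
    """Remove the ancestor-side annotation of redundant pairs.

    Under the default policy only same-evidence pairs lose their ancestor,
    since a differently evidenced parent (e.g. experimental support) is kept
    alongside the more specific child.  ``drop_ancestor_all`` removes every
    ancestor-side record regardless of evidence.
    """
    if policy not in REDUNDANCY_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {REDUNDANCY_POLICIES}")
    doomed = {
        pair.ancestor_annotation
        for pair in pairs
        if policy == "drop_ancestor_all" or pair.same_evidence
    }
    kept = [r for r in annotations.records if r not in doomed]
    log = [(r, "redundant ancestor removed") for r in annotations.records if r in doomed]
    return (
        AnnotationSet(records=kept, source_label=annotations.source_label),
        log,
    )


def correct_domain_and_taxon(
    flagged: Iterable[Flag],
    annotations: AnnotationSet,
) -> tuple[AnnotationSet, list[tuple[AnnotationRecord, str]]]:
    """Drop domain- and taxonomy-inconsistent records, logging each removal."""
    doomed: dict[AnnotationRecord, Flag] = {}
    for flag in flagged:
        doomed.setdefault(flag.record, flag)
    kept = [r for r in annotations.records if r not in doomed]
    log = [
        (r, f"{doomed[r].kind}: {doomed[r].detail}")
        for r in annotations.records
        if r in doomed
    ]
    return (
        AnnotationSet(records=kept, source_label=annotations.source_label),
        log,
    )


# -- summary --------------------------------------------------------------


def _counts(records: Iterable[AnnotationRecord]) -> LevelCounts:
    records = list(records)
    return LevelCounts(
        gene_products=len({r.gene_key for r in records}),
        annotations=len(set(records)),
        terms=len({r.go_id for r in records}),
    )


def summarize(
    pairs: Sequence[RedundantPair],
    domain_flags: Sequence[Flag],
    taxon_flags: Sequence[Flag],
    annotations: AnnotationSet,
) -> InconsistencyReport:
    """Three-level summary (gene products / annotations / terms) per database.

    Counting convention for redundancy: the ancestor-side annotation of each
    pair is *the* redundant annotation, so annotation-level counts are
    distinct ancestor-side records and term-level counts distinct
    ancestor-side terms; the same-evidence restriction is reported alongside.
    """
    flagged: list[Flag] = []
    per_db: dict[str, dict[str, list[AnnotationRecord]]] = {}

    def bucket(label: str, kind: str) -> list[AnnotationRecord]:
        return per_db.setdefault(label, {}).setdefault(kind, [])

    seen_ancestors: set[AnnotationRecord] = set()
    for pair in pairs:
        rec = pair.ancestor_annotation
        bucket(rec.db, "redundant").append(rec)
        if pair.same_evidence:
            bucket(rec.db, "redundant_same_evidence").append(rec)
        if rec not in seen_ancestors:
            seen_ancestors.add(rec)
            flagged.append(
                Flag(rec, "redundant", f"ancestor of {pair.descendant_annotation.go_id}")
            )
    for flag in list(domain_flags) + list(taxon_flags):
        bucket(flag.record.db, flag.kind).append(flag.record)
        flagged.append(flag)

    summary: dict[str, dict[str, LevelCounts]] = {}
    kinds = ["redundant", "redundant_same_evidence", "domain", "taxon"]
    for label in sorted({r.db for r in annotations.records} | set(per_db)):
        summary[label] = {}
        all_flagged: list[AnnotationRecord] = []
        for kind in kinds:
            records = per_db.get(label, {}).get(kind, [])
            summary[label][kind] = _counts(records)
            if kind != "redundant_same_evidence":
                all_flagged.extend(records)
        summary[label]["total"] = _counts(all_flagged)

    totals: dict[str, LevelCounts] = {}
    for kind in kinds:
        records = [r for db in per_db.values() for r in db.get(kind, [])]
        totals[kind] = _counts(records)
    totals["total"] = _counts(
        [
            r
            for db in per_db.values()
            for kind, recs in db.items()
            if kind != "redundant_same_evidence"
            for r in recs
        ]
    )
    return InconsistencyReport(flagged=flagged, summary=summary, totals=totals)
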