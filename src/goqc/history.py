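"""Ontology release diffing, per-term change histories, and stale-ID rewriting.

Two consecutive releases are diffed into classified change records covering
ten change types: the six monthly-report types (new term, new obsoletion,
term name change, new definition, new term merge, term movement) plus the
four report types added later by ontology-editor tooling (change comment,
change synonym, change category, change external reference).

A term that becomes obsolete or is merged away in the new release emits only
its ``new_obsoletion`` / ``new_term_merge`` record: the status change subsumes
any simultaneous attribute edits (an obsoletion necessarily clears the parent
set, for instance), and suppressing the secondary records keeps the diff in
one-to-one correspondence with the edits actually applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .annotations import AnnotationRecord, AnnotationSet
from .ontology import OntologyGraph, resolve_id

logger = logging.getLogger("goqc")

CHANGE_TYPES = (
    "new_term",
    "new_obsoletion",
    "term_name_change",
    "new_definition",
    "new_term_merge",
    "term_movement",
    "change_comment",
    "change_synonym",
    "change_category",
    "change_external_reference",
)

STATUS_AFFECTING = {"new_obsoletion", "new_term_merge"}


@dataclass(frozen=True)
class ChangeRecord:
    change_type: str
    go_id: str
    old_value: str | None = None
    new_value: str | None = None
    from_version: str = ""
    to_version: str = ""


@dataclass
class TermHistory:
    go_id: str
    records: list[ChangeRecord] = field(default_factory=list)
    current_status: str = "active"  # active | obsolete | merged


def _parent_repr(term) -> str:
    return ",".join(f"{rel}:{parent}" for rel, parent in sorted(term.parents))


def diff_releases(old: OntologyGraph, new: OntologyGraph) -> list[ChangeRecord]:
    """Classify every edit between two validated releases.

    Identity of a term id across releases:
    * present only in the new release (and not an old alt_id) -> new_term;
    * primary in old, alt_id of a survivor in new -> new_term_merge;
    * obsolete flag turned on -> new_obsoletion;
    * otherwise field-by-field comparison yields the attribute change types.
    """
    out: list[ChangeRecord] = []

    def rec(change_type: str, go_id: str, old_value=None, new_value=None):
        out.append(
            ChangeRecord(
                change_type=change_type,
                go_id=go_id,
                old_value=old_value,
                new_value=new_value,
                from_version=old.version_label,
                to_version=new.version_label,
            )
        )

    old_alts = set(old._alt_index)
    for go_id, term in new.terms.items():
        if go_id not in old.terms and go_id not in old_alts:
            rec("new_term", go_id, new_value=term.name)

    for go_id, old_term in old.terms.items():
        if go_id not in new.terms:
            merged_into = new._alt_index.get(go_id)
            if merged_into is not None:
                rec("new_term_merge", go_id, old_value=go_id, new_value=merged_into)
            else:
                logger.warning("term %s disappeared without a merge target", go_id)
            continue
        new_term = new.terms[go_id]
        if not old_term.is_obsolete and new_term.is_obsolete:
            rec("new_obsoletion", go_id, old_value=old_term.name)
            continue  # obsoletion subsumes simultaneous attribute edits
        if old_term.name != new_term.name:
            rec("term_name_change", go_id, old_term.name, new_term.name)
        if old_term.definition != new_term.definition:
            rec("new_definition", go_id, old_term.definition, new_term.definition)
        if sorted(old_term.parents) != sorted(new_term.parents):
            rec("term_movement", go_id, _parent_repr(old_term), _parent_repr(new_term))
        if old_term.comment != new_term.comment:
            rec("change_comment", go_id, old_term.comment, new_term.comment)
        if sorted(old_term.synonyms) != sorted(new_term.synonyms):
            rec(
                "change_synonym",
                go_id,
                ";".join(sorted(old_term.synonyms)),
                ";".join(sorted(new_term.synonyms)),
            )
        if old_term.namespace != new_term.namespace:
            rec("change_category", go_id, old_term.namespace, new_term.namespace)
        if sorted(old_term.xrefs) != sorted(new_term.xrefs):
            rec(
                "change_external_reference",
                go_id,
                ";".join(sorted(old_term.xrefs)),
                ";".join(sorted(new_term.xrefs)),
            )
    return out


def term_history(
    all_records: Sequence[ChangeRecord],
    go_id: str,
    latest: OntologyGraph | None = None,
) -> TermHistory:
    """Version-ordered records touching one id, with its derived status.

    Records merging other ids *into* ``go_id`` are included (they are part of
    its evolution) but only a merge *of* ``go_id`` itself changes its status.
    ``all_records`` must already be ordered by release pair, as produced by
    diffing consecutive releases in sequence.
    """
    touching = [
        r
        for r in all_records
        if r.go_id == go_id
        or (r.change_type == "new_term_merge" and r.new_value == go_id)
    ]
    status = "active"
    for r in touching:
        if r.change_type == "new_obsoletion" and r.go_id == go_id:
            status = "obsolete"
        elif r.change_type == "new_term_merge" and r.go_id == go_id:
            status = "merged"
        elif r.go_id == go_id and r.change_type == "new_term":
            status = "active"
    if not touching and latest is not None:
        res = resolve_id(latest, go_id)
        status = {"primary": "active", "obsolete": "obsolete", "merged": "merged"}.get(
            res.status, "active"
        )
    return TermHistory(go_id=go_id, records=touching, current_status=status)


def rewrite_annotation_ids(
    annotations: AnnotationSet,
    latest: OntologyGraph,
    apply_obsolete_replacements: bool = False,
) -> tuple[AnnotationSet, list[tuple[AnnotationRecord, str]]]:
    """Redirect stale accessions against the latest release.

    Merged accessions are rewritten to their canonical id.  Obsolete
    accessions are *not* rewritten by default — ``replaced_by``/``consider``
    entries are suggestions, not equivalences — and are logged with their
    candidates; with ``apply_obsolete_replacements=True`` an obsolete id with
    exactly one ``replaced_by`` candidate is rewritten to it.  Unknown ids are
    logged untouched.  The operation is idempotent.
    """
    out: list[AnnotationRecord] = []
    log: list[tuple[AnnotationRecord, str]] = []
    for record in annotations.records:
        res = resolve_id(latest, record.go_id)
        if res.status == "merged":
            out.append(record.with_go_id(res.canonical))
            log.append((record, f"merged id rewritten to {res.canonical}"))
        elif res.status == "obsolete":
            replaced = latest.terms[record.go_id].replaced_by
            if apply_obsolete_replacements and len(replaced) == 1:
                out.append(record.with_go_id(replaced[0]))
                log.append((record, f"obsolete id replaced by {replaced[0]}"))
            else:
                out.append(record)
                log.append(
                    (record, f"obsolete id; candidates: {','.join(res.candidates) or 'none'}")
                )
        elif res.status == "unknown":
            out.append(record)
            log.append((record, "unknown id"))
        else:
            out.append(record)
    return (
        AnnotationSet(records=out, source_label=annotations.source_label),
        log,
    )
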