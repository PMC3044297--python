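"""Gene Ontology DAG: OBO parsing, ancestry queries, and accession resolution.

The Gene Ontology is a directed acyclic graph (DAG) of terms connected by
typed relationships.  Under the true-path rule an annotation to a term is an
implicit annotation to every ancestor of that term, which is why ancestry
queries sit at the core of redundancy detection.

Only a durable subset of the OBO 1.2 flat-file dialect is honored: ``[Term]``
stanzas with id / name / namespace / def / comment / synonym / xref /
is_obsolete / alt_id / replaced_by / consider / is_a / relationship tags.
``[Typedef]`` stanzas are skipped with a logged notice.  ``is_a`` and
``relationship: part_of`` become ancestry edges by default; other relationship
types (``regulates`` etc.) are stored but excluded from ancestry unless
explicitly requested.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger("goqc")

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Relations that carry true-path ancestry by default.
ANCESTRY_RELATIONS = frozenset({"is_a", "part_of"})

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OboFormatError(ValueError):
    """Malformed OBO content (bad accession, duplicate id, bad tag value)."""


class StructuralError(ValueError):
    """Graph-level violation: cycle, dangling parent, alt_id collision."""


class UnknownTermError(KeyError):
    """Lookup of an accession that is not a primary id in the graph."""


@dataclass
class Term:
    """One GO term as carried by the OBO subset."""

    id: str
    name: str = ""
    namespace: str = "biological_process"
    definition: str | None = None
    comment: str | None = None
    synonyms: list[str] = field(default_factory=list)
    xrefs: list[str] = field(default_factory=list)
    is_obsolete: bool = False
    alt_ids: list[str] = field(default_factory=list)
    replaced_by: list[str] = field(default_factory=list)
    consider: list[str] = field(default_factory=list)
    #: Typed parent edges: (relation, parent accession).
    parents: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class Resolution:
    """Outcome of resolving a GO accession against a graph."""

    status: str  # primary | merged | obsolete | unknown
    canonical: str | None = None
    candidates: list[str] = field(default_factory=list)


class OntologyGraph:
    """A validated GO DAG.

    Parameters
    ----------
    terms:
        Iterable of :class:`Term`; primary ids must be unique.
    version_label:
        Opaque release label (e.g. a date) used by the history module.
    """

    def __init__(self, terms: Iterable[Term], version_label: str = ""):
        self.terms: dict[str, Term] = {}
        self.version_label = version_label
        for term in terms:
            if term.id in self.terms:
                raise OboFormatError(f"duplicate primary id {term.id}")
            self.terms[term.id] = term
        self._alt_index: dict[str, str] = {}
        self._build_alt_index()
        self._dag = self._build_dag()
        self._validate()

    # -- construction ----------------------------------------------------

    def _build_alt_index(self) -> None:
        for term in self.terms.values():
            for alt in term.alt_ids:
                if alt in self.terms:
                    raise StructuralError(
                        f"alt_id {alt} of {term.id} collides with a primary id"
                    )
                if alt in self._alt_index:
                    raise StructuralError(
                        f"alt_id {alt} claimed by both {self._alt_index[alt]} "
                        f"and {term.id}"
                    )
                self._alt_index[alt] = term.id

    def _build_dag(self) -> nx.DiGraph:
        dag = nx.DiGraph()
        dag.add_nodes_from(self.terms)
        for term in self.terms.values():
            for relation, parent in term.parents:
                if relation in ANCESTRY_RELATIONS:
                    dag.add_edge(term.id, parent, relation=relation)
        return dag

    def _validate(self) -> None:
        for term in self.terms.values():
            if not term.is_obsolete:
                for _, parent in term.parents:
                    if parent not in self.terms:
                        raise StructuralError(
                            f"term {term.id} references missing parent {parent}"
                        )
        try:
            cycle = nx.find_cycle(self._dag)
        except nx.NetworkXNoCycle:
            return
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise StructuralError(f"ancestry cycle detected: {path}")

    # -- queries ---------------------------------------------------------

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, go_id: str) -> Term:
        try:
            return self.terms[go_id]
        except KeyError:
            raise UnknownTermError(go_id) from None

    @property
    def n_ancestry_edges(self) -> int:
        return self._dag.number_of_edges()


def parse_obo(source: str | IO[str], version_label: str = "") -> OntologyGraph:
    """Parse OBO 1.2-style stanza text into a validated :class:`OntologyGraph`.

    ``source`` may be a file-like object or a string of OBO text.
    """
    if isinstance(source, str):
        source = io.StringIO(source)

    terms: list[Term] = []
    current: Term | None = None
    in_term_stanza = False
    header_version = ""

    def flush() -> None:
        nonlocal current
        if current is not None:
            if not GO_ID_RE.match(current.id):
                raise OboFormatError(f"bad GO accession {current.id!r}")
            terms.append(current)
            current = None

    for raw in source:
        line = raw.rstrip("\n").strip()
        if line.startswith("!"):
            continue
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term_stanza = line == "[Term]"
            if not in_term_stanza:
                logger.info("skipping %s stanza", line)
                continue
            current = None
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.strip()
        if not in_term_stanza:
            if tag == "data-version":
                header_version = value
            continue
        if tag == "id":
            flush()
            current = Term(id=value)
            continue
        if current is None:
            raise OboFormatError(f"tag {tag!r} before id in [Term] stanza")
        if tag == "name":
            current.name = value
        elif tag == "namespace":
            current.namespace = value
        elif tag == "def":
            current.definition = value
        elif tag == "comment":
            current.comment = value
        elif tag == "synonym":
            current.synonyms.append(value)
        elif tag == "xref":
            current.xrefs.append(value)
        elif tag == "is_obsolete":
            current.is_obsolete = value.lower() == "true"
        elif tag == "alt_id":
            current.alt_ids.append(value)
        elif tag == "replaced_by":
            current.replaced_by.append(value)
        elif tag == "consider":
            current.consider.append(value)
        elif tag == "is_a":
            parent = value.split("!", 1)[0].strip()
            current.parents.append(("is_a", parent))
        elif tag == "relationship":
            parts = value.split("!", 1)[0].split()
            if len(parts) != 2:
                raise OboFormatError(f"bad relationship line {line!r}")
            current.parents.append((parts[0], parts[1]))
        # unrecognized tags are ignored (created_by, subset, ...)
    flush()
    return OntologyGraph(terms, version_label=version_label or header_version)


def write_obo(graph: OntologyGraph, stream: IO[str]) -> None:
    """Serialize the canonical OBO subset; round-trips through parse_obo."""
    stream.write("format-version: 1.2\n")
    if graph.version_label:
        stream.write(f"data-version: {graph.version_label}\n")
    for go_id in sorted(graph.terms):
        term = graph.terms[go_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {term.id}\n")
        stream.write(f"name: {term.name}\n")
        stream.write(f"namespace: {term.namespace}\n")
        for alt in term.alt_ids:
            stream.write(f"alt_id: {alt}\n")
        if term.definition is not None:
            stream.write(f"def: {term.definition}\n")
        if term.comment is not None:
            stream.write(f"comment: {term.comment}\n")
        for syn in term.synonyms:
            stream.write(f"synonym: {syn}\n")
        for xref in term.xrefs:
            stream.write(f"xref: {xref}\n")
        for relation, parent in term.parents:
            if relation == "is_a":
                stream.write(f"is_a: {parent}\n")
            else:
                stream.write(f"relationship: {relation} {parent}\n")
        if term.is_obsolete:
            stream.write("is_obsolete: true\n")
        for rep in term.replaced_by:
            stream.write(f"replaced_by: {rep}\n")
        for con in term.consider:
            stream.write(f"consider: {con}\n")


def ancestors(
    graph: OntologyGraph,
    go_id: str,
    relations: frozenset[str] | set[str] = ANCESTRY_RELATIONS,
) -> set[str]:
    """All proper ancestors of ``go_id`` reachable via ``relations``.

    Obsolete terms carry no parents, so their ancestor set is empty; the
    query never traverses an edge whose relation is outside ``relations``.
    """
    term = graph.term(go_id)
    if term.is_obsolete:
        return set()
    out: set[str] = set()
    stack = [go_id]
    while stack:
        node = stack.pop()
        for relation, parent in graph.terms[node].parents:
            if relation in relations and parent not in out:
                out.add(parent)
                if parent in graph.terms:
                    stack.append(parent)
    out.discard(go_id)
    return out


def resolve_id(graph: OntologyGraph, go_id: str) -> Resolution:
    """Classify an accession as primary / merged / obsolete / unknown.

    A merged accession (found among some surviving term's ``alt_id`` list) is
    redirected to that term; an obsolete accession reports its
    ``replaced_by``/``consider`` lists as replacement candidates.  Unknown is
    a status, not an error.
    """
    if go_id in graph.terms:
        term = graph.terms[go_id]
        if term.is_obsolete:
            return Resolution(
                "obsolete",
                canonical=None,
                candidates=list(term.replaced_by) + list(term.consider),
            )
        return Resolution("primary", canonical=go_id)
    if go_id in graph._alt_index:
        return Resolution("merged", canonical=graph._alt_index[go_id])
    return Resolution("unknown")


def namespace_roots(graph: OntologyGraph) -> dict[str, set[str]]:
    """Non-obsolete terms with zero ancestry parents, grouped by namespace."""
    roots: dict[str, set[str]] = {}
    for term in graph.terms.values():
        if term.is_obsolete:
            continue
        if not any(rel in ANCESTRY_RELATIONS for rel, _ in term.parents):
            roots.setdefault(term.namespace, set()).add(term.id)
    return roots
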