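"""NCBI-style taxonomy: taxdump parsing, lineage, and superkingdom queries.

The prokaryote/eukaryote split used by domain-inconsistency detection is
defined over the superkingdom rank: Bacteria and Archaea are prokaryotic,
Eukaryota is eukaryotic, and anything without a superkingdom-ranked ancestor
(viruses, unclassified sequences) maps to ``other`` and is never flagged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO

PROKARYOTE_SUPERKINGDOMS = frozenset({"Bacteria", "Archaea"})


class TaxonomyStructuralError(ValueError):
    """Orphan parent reference, cycle, or missing/multiple roots."""


class UnknownTaxonError(KeyError):
    """Lookup of a taxid absent from the tree."""


@dataclass
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str = ""


class TaxonomyTree:
    """Rooted taxon tree; the root is its own parent (NCBI convention)."""

    def __init__(self, nodes: dict[int, TaxonNode] | list[TaxonNode]):
        if isinstance(nodes, list):
            nodes = {n.taxid: n for n in nodes}
        self.nodes: dict[int, TaxonNode] = dict(nodes)
        roots = [t for t, n in self.nodes.items() if n.parent_taxid == t]
        if len(roots) != 1:
            raise TaxonomyStructuralError(
                f"expected exactly one root (parent == self), found {roots}"
            )
        self.root = roots[0]
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyStructuralError(
                    f"taxid {node.taxid} references missing parent "
                    f"{node.parent_taxid}"
                )
        # every parent chain must terminate at the root (detects cycles)
        resolved: set[int] = {self.root}
        for taxid in self.nodes:
            chain = []
            node = taxid
            while node not in resolved:
                chain.append(node)
                node = self.nodes[node].parent_taxid
                if node in chain:
                    raise TaxonomyStructuralError(
                        f"cycle in parent chain at taxid {node}"
                    )
            resolved.update(chain)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None


def parse_taxdump(nodes_stream: str | IO[str], names_stream: str | IO[str]) -> TaxonomyTree:
    """Parse NCBI ``nodes.dmp`` / ``names.dmp`` dialect into a tree.

    Fields are separated by ``\\t|\\t`` and rows terminated by ``\\t|``; only
    ``scientific name`` rows of names.dmp are merged in.
    """
    if isinstance(nodes_stream, str):
        nodes_stream = io.StringIO(nodes_stream)
    if isinstance(names_stream, str):
        names_stream = io.StringIO(names_stream)

    nodes: dict[int, TaxonNode] = {}
    for raw in nodes_stream:
        raw = raw.rstrip("\n")
        if not raw.strip():
            continue
        fields = [f.strip() for f in raw.rstrip("\t|").split("\t|\t")]
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        nodes[taxid] = TaxonNode(taxid=taxid, parent_taxid=parent, rank=rank)
    for raw in names_stream:
        raw = raw.rstrip("\n")
        if not raw.strip():
            continue
        fields = [f.strip() for f in raw.rstrip("\t|").split("\t|\t")]
        if len(fields) >= 4 and fields[3] == "scientific name":
            taxid = int(fields[0])
            if taxid in nodes:
                nodes[taxid].scientific_name = fields[1]
    return TaxonomyTree(nodes)


def parse_taxonomy_tsv(stream: str | IO[str]) -> TaxonomyTree:
    """Parse the simplified 4-column fixture dialect: taxid, parent, rank, name."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    nodes: dict[int, TaxonNode] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        taxid, parent, rank, name = line.split("\t")
        nodes[int(taxid)] = TaxonNode(int(taxid), int(parent), rank, name)
    return TaxonomyTree(nodes)


def write_taxonomy_tsv(tree: TaxonomyTree, stream: IO[str]) -> None:
    for taxid in sorted(tree.nodes):
        n = tree.nodes[taxid]
        stream.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.scientific_name}\n")


def lineage(tree: TaxonomyTree, taxid: int) -> list[int]:
    """Ordered taxids from the root down to ``taxid`` (inclusive)."""
    tree.node(taxid)
    path = [taxid]
    while taxid != tree.root:
        taxid = tree.nodes[taxid].parent_taxid
        path.append(taxid)
    path.reverse()
    return path


def is_descendant(tree: TaxonomyTree, taxid: int, ancestor_taxid: int) -> bool:
    """True iff ``ancestor_taxid`` lies on the lineage of ``taxid``.

    Inclusive: every taxon is its own descendant, which is what species-level
    restrictions require.
    """
    tree.node(ancestor_taxid)
    return ancestor_taxid in lineage(tree, taxid)


def superkingdom_of(tree: TaxonomyTree, taxid: int) -> str:
    """The superkingdom-ranked ancestor name, or ``"other"`` when none exists."""
    for node_id in lineage(tree, taxid):
        node = tree.nodes[node_id]
        if node.rank == "superkingdom":
            name = node.scientific_name
            if name in ("Bacteria", "Archaea", "Eukaryota"):
                return name
            return "other"
    return "other"


def is_prokaryote(tree: TaxonomyTree, taxid: int) -> bool:
    return superkingdom_of(tree, taxid) in PROKARYOTE_SUPERKINGDOMS


def is_eukaryote(tree: TaxonomyTree, taxid: int) -> bool:
    return superkingdom_of(tree, taxid) == "Eukaryota"
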