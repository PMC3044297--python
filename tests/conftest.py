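"""Shared fixtures: a 5-term diamond ontology, a toy taxonomy, a toy GAF,
and independent brute-force oracles used across modules."""

from __future__ import annotations

import pytest

from goqc import parse_obo, parse_taxonomy_tsv, read_gaf

# A ← B, A ← C, B ← D, C ← D (D's edge to C is part_of), E obsolete.
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: branch b
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: branch c
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000004
name: leaf d
namespace: biological_process
alt_id: GO:0000014
is_a: GO:0000002
relationship: part_of GO:0000003

[Term]
id: GO:0000005
name: retired term e
namespace: biological_process
is_obsolete: true
replaced_by: GO:0000004
"""

# root → Bacteria → Proteobacteria → E. coli; root → Eukaryota → {human, worm};
# root → Archaea → archaeon; root → Viruses (no superkingdom rank) → phage.
TOY_TAXONOMY_TSV = """\
1\t1\tno rank\troot
2\t1\tsuperkingdom\tBacteria
1224\t2\tphylum\tProteobacteria
562\t1224\tspecies\tEscherichia coli
210\t1224\tspecies\tHelicobacter pylori
2157\t1\tsuperkingdom\tArchaea
2287\t2157\tspecies\tSulfolobus acidocaldarius
2759\t1\tsuperkingdom\tEukaryota
9606\t2759\tspecies\tHomo sapiens
6239\t2759\tspecies\tCaenorhabditis elegans
10239\t1\tclade\tViruses
10710\t10239\tspecies\tLambdavirus
"""

TOY_GAF = """\
!gaf-version: 2.2
UniProt\tP00001\tgene1\t\tGO:0000004\tPMID:1\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20100101\tUniProt\t\t
UniProt\tP00001\tgene1\t\tGO:0000001\tPMID:1\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20100101\tUniProt\t\t
MGI\tM00007\tgene7\tNOT\tGO:0000002\tPMID:2\tIDA\t\tP\t\t\tprotein\ttaxon:562|taxon:9606\t20100101\tMGI\t\t
"""


@pytest.fixture
def diamond():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture
def toy_tree():
    return parse_taxonomy_tsv(TOY_TAXONOMY_TSV)


@pytest.fixture
def toy_gaf():
    return read_gaf(TOY_GAF)


def brute_force_ancestors(graph, go_id, relations=frozenset({"is_a", "part_of"})):
    """Independent oracle: enumerate every directed path by recursion on the
    raw parent lists (no shared traversal code with the implementation)."""
    out = set()

    def walk(node):
        for relation, parent in graph.terms[node].parents:
            if relation in relations:
                out.add(parent)
                if parent in graph.terms:
                    walk(parent)

    walk(go_id)
    out.discard(go_id)
    return out


def brute_force_redundant(graph, annotations):
    """Oracle for redundancy: all annotation pairs x full transitive closure."""
    from goqc import resolve_id

    def canon(go_id):
        res = resolve_id(graph, go_id)
        return {"primary": go_id, "merged": res.canonical}.get(res.status)

    groups = {}
    for rec in annotations.records:
        if "NOT" in rec.qualifier:
            continue
        groups.setdefault(rec.gene_key, []).append(rec)
    found = set()
    for records in groups.values():
        for anc_rec in records:
            for desc_rec in records:
                if anc_rec is desc_rec:
                    continue
                a, d = canon(anc_rec.go_id), canon(desc_rec.go_id)
                if a is None or d is None:
                    continue
                if not graph.terms[d].is_obsolete and a in brute_force_ancestors(graph, d):
                    found.add((anc_rec, desc_rec))
    return found
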