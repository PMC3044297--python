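"""Synthetic ontologies, taxonomies, and annotation corpora with planted errors.

Every detector in this package is tested against corpora generated here: a
random rooted DAG of GO-style terms, a small NCBI-style taxonomy with the
three superkingdoms plus a virus branch, domain-restricted term lists,
taxon restrictions, and an annotation set whose background is *consistent by
construction* (terms are drawn by rejection sampling so that no background
record is redundant, domain-inconsistent, or restriction-violating).  Known
inconsistencies are then injected with exact bookkeeping, so each detector
must recover precisely the planted set.

The generator emulates the statistical shape of a multi-database annotation
corpus — several source databases, mixed evidence codes dominated by
electronic annotation, mixed taxa — not the topology statistics of the real
ontology; structural validity and exact ground truth are what matter here.
"""

from __future__ import annotations

import copy
import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .annotations import AnnotationRecord, AnnotationSet, write_gaf
from .inconsistency import DomainTermLists, RedundantPair, TaxonRestriction
from .ontology import OntologyGraph, Term, ancestors, write_obo
from .taxonomy import TaxonNode, TaxonomyTree, is_descendant, superkingdom_of, write_taxonomy_tsv


class FixtureSpecError(ValueError):
    """The requested corpus is infeasible (e.g. plants without list terms)."""


@dataclass
class FixtureSpec:
    """Parameters of one synthetic corpus.

    Defaults describe the demo corpus: a 40-term ontology, a 12-taxon tree
    spanning the three superkingdoms plus viruses, 4 source databases and 200
    annotations with an evidence mix dominated by IEA — the code the
    inconsistency analysis singles out — over a base of experimental and
    curated codes.
    """

    seed: int = 0
    n_terms: int = 40
    max_parents: int = 3
    n_taxa: int = 12
    n_gene_products: int = 30
    n_annotations: int = 200
    n_databases: int = 4
    planted_redundant_same_ev: int = 0
    planted_redundant_diff_ev: int = 0
    planted_domain_inconsistent: int = 0
    planted_taxon_inconsistent: int = 0
    planted_merges: int = 2
    planted_obsoletions: int = 2
    n_eukaryote_only_terms: int = 5
    n_prokaryote_only_terms: int = 3
    n_restrictions: int = 4
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "IEA": 6.0, "IDA": 2.0, "ISS": 2.0, "TAS": 1.0,
            "IMP": 1.0, "IGI": 0.5, "NAS": 0.5, "NA": 0.5,
        }
    )

    def __post_init__(self) -> None:
        planted_records = (
            2 * (self.planted_redundant_same_ev + self.planted_redundant_diff_ev)
            + self.planted_domain_inconsistent
            + self.planted_taxon_inconsistent
        )
        if planted_records > self.n_annotations:
            raise FixtureSpecError(
                f"planted records ({planted_records}) exceed n_annotations "
                f"({self.n_annotations})"
            )
        if not self.evidence_mix or all(w <= 0 for w in self.evidence_mix.values()):
            raise FixtureSpecError("evidence_mix must have a positive weight")
        if any(w < 0 for w in self.evidence_mix.values()):
            raise FixtureSpecError("evidence_mix weights must be nonnegative")
        if self.planted_domain_inconsistent and not (
            self.n_eukaryote_only_terms or self.n_prokaryote_only_terms
        ):
            raise FixtureSpecError("domain plants requested but domain lists empty")
        if self.planted_taxon_inconsistent and not self.n_restrictions:
            raise FixtureSpecError("taxon plants requested but no restrictions")


@dataclass
class GroundTruth:
    """Exact planted instances, the contract every detector is held to."""

    redundant_pairs: list[RedundantPair] = field(default_factory=list)
    domain_records: list[AnnotationRecord] = field(default_factory=list)
    taxon_records: list[AnnotationRecord] = field(default_factory=list)
    merged_ids: dict[str, str] = field(default_factory=dict)
    obsolete_ids: list[str] = field(default_factory=list)
    edits: list[tuple[str, str]] = field(default_factory=list)


def _go(i: int) -> str:
    return f"GO:{i:07d}"


# -- ontology -------------------------------------------------------------


def generate_ontology(spec: FixtureSpec, rng: random.Random | None = None) -> tuple[OntologyGraph, GroundTruth]:
    """Random rooted DAG, acyclic by construction (parents precede children).

    Also plants merged accessions (alt_ids in the 0900001+ range) and
    obsolete terms with a replaced_by pointer, recorded in the ground truth
    for resolve/rewrite tests.
    """
    if spec.n_terms < 1:
        raise FixtureSpecError("n_terms must be >= 1")
    rng = rng or random.Random(spec.seed)
    terms: list[Term] = [Term(id=_go(1), name="term 1", namespace="biological_process")]
    for i in range(2, spec.n_terms + 1):
        n_parents = rng.randint(1, min(spec.max_parents, i - 1))
        parent_idx = rng.sample(range(1, i), n_parents)
        parents = [
            ("part_of" if rng.random() < 0.15 else "is_a", _go(j))
            for j in sorted(parent_idx)
        ]
        terms.append(
            Term(
                id=_go(i),
                name=f"term {i}",
                namespace="biological_process",
                parents=parents,
            )
        )
    truth = GroundTruth()
    active_ids = [t.id for t in terms]
    for m in range(spec.planted_merges):
        alt = _go(900001 + m)
        target = rng.choice(active_ids)
        next(t for t in terms if t.id == target).alt_ids.append(alt)
        truth.merged_ids[alt] = target
    next_id = spec.n_terms + 1
    for _ in range(spec.planted_obsoletions):
        obs_id = _go(next_id)
        next_id += 1
        replacement = rng.choice(active_ids)
        terms.append(
            Term(
                id=obs_id,
                name=f"obsolete term {obs_id}",
                namespace="biological_process",
                is_obsolete=True,
                replaced_by=[replacement],
            )
        )
        truth.obsolete_ids.append(obs_id)
    return OntologyGraph(terms, version_label="r1"), truth


# -- taxonomy -------------------------------------------------------------

ROOT_TAXID = 1
BACTERIA, ARCHAEA, EUKARYOTA, VIRUSES = 2, 2157, 2759, 10239


def generate_taxonomy(spec: FixtureSpec, rng: random.Random | None = None) -> TaxonomyTree:
    """Fixed superkingdom skeleton plus randomly assigned species leaves."""
    rng = rng or random.Random(spec.seed + 1)
    nodes = {
        ROOT_TAXID: TaxonNode(ROOT_TAXID, ROOT_TAXID, "no rank", "root"),
        BACTERIA: TaxonNode(BACTERIA, ROOT_TAXID, "superkingdom", "Bacteria"),
        ARCHAEA: TaxonNode(ARCHAEA, ROOT_TAXID, "superkingdom", "Archaea"),
        EUKARYOTA: TaxonNode(EUKARYOTA, ROOT_TAXID, "superkingdom", "Eukaryota"),
        VIRUSES: TaxonNode(VIRUSES, ROOT_TAXID, "clade", "Viruses"),
    }
    n_species = max(0, spec.n_taxa - len(nodes))
    kingdoms = [BACTERIA, ARCHAEA, EUKARYOTA, VIRUSES]
    for i in range(n_species):
        taxid = 10001 + i
        if i < 2:
            # always cover both biological domains so domain/taxon
            # inconsistencies are plantable even in tiny trees
            parent = (BACTERIA, EUKARYOTA)[i]
        else:
            # bias towards bacteria/eukaryotes, as in real annotation corpora
            parent = rng.choices(kingdoms, weights=[4, 1, 5, 1])[0]
        nodes[taxid] = TaxonNode(taxid, parent, "species", f"species {taxid}")
    return TaxonomyTree(nodes)


# -- lists and restrictions -----------------------------------------------


def generate_domain_lists(
    spec: FixtureSpec, graph: OntologyGraph, rng: random.Random
) -> DomainTermLists:
    active = sorted(t.id for t in graph.terms.values() if not t.is_obsolete)
    want = spec.n_eukaryote_only_terms + spec.n_prokaryote_only_terms
    if want > len(active):
        raise FixtureSpecError("not enough terms for the requested domain lists")
    chosen = rng.sample(active, want)
    return DomainTermLists(
        eukaryote_only=set(chosen[: spec.n_eukaryote_only_terms]),
        prokaryote_only=set(chosen[spec.n_eukaryote_only_terms:]),
    )


def generate_restrictions(
    spec: FixtureSpec,
    graph: OntologyGraph,
    tree: TaxonomyTree,
    lists: DomainTermLists,
    rng: random.Random,
) -> list[TaxonRestriction]:
    """Restrictions on terms disjoint from the domain lists, one per term."""
    listed = lists.eukaryote_only | lists.prokaryote_only
    pool = sorted(
        t.id for t in graph.terms.values() if not t.is_obsolete and t.id not in listed
    )
    if spec.n_restrictions > len(pool):
        raise FixtureSpecError("not enough terms for the requested restrictions")
    species = [t for t, n in tree.nodes.items() if n.rank == "species"]
    combos = []
    for group in (BACTERIA, ARCHAEA, EUKARYOTA):
        if group not in tree:
            continue
        inside = [s for s in species if is_descendant(tree, s, group)]
        outside = [s for s in species if not is_descendant(tree, s, group)]
        # keep only restrictions that some species satisfies and some violates,
        # so both consistent backgrounds and planted violations are possible
        if inside and outside:
            combos.append(("only_in", group))
            combos.append(("never_in", group))
    if spec.n_restrictions and not combos:
        raise FixtureSpecError("taxonomy too small for violable restrictions")
    out = []
    for go_id in rng.sample(pool, spec.n_restrictions):
        mode, group = rng.choice(combos)
        out.append(TaxonRestriction(go_id, mode, group))
    return out


# -- annotations ----------------------------------------------------------

_RETRY_CAP = 500


def _term_consistent(
    go_id: str,
    taxid: int,
    tree: TaxonomyTree,
    lists: DomainTermLists,
    by_term: dict[str, list[TaxonRestriction]],
) -> bool:
    kingdom = superkingdom_of(tree, taxid)
    if go_id in lists.eukaryote_only and kingdom in ("Bacteria", "Archaea"):
        return False
    if go_id in lists.prokaryote_only and kingdom == "Eukaryota":
        return False
    for restriction in by_term.get(go_id, ()):
        desc = is_descendant(tree, taxid, restriction.taxon_id)
        if restriction.mode == "only_in" and not desc:
            return False
        if restriction.mode == "never_in" and desc:
            return False
    return True


def generate_annotations(
    spec: FixtureSpec,
    graph: OntologyGraph,
    tree: TaxonomyTree,
    lists: DomainTermLists,
    restrictions: list[TaxonRestriction],
    rng: random.Random | None = None,
) -> tuple[AnnotationSet, GroundTruth]:
    """Consistent background plus exactly the requested planted errors.

    Background terms for one gene product are mutually ancestry-free and
    consistent with the gene's taxon; each planted inconsistency lives on a
    dedicated gene product so it produces exactly one detector hit.
    """
    rng = rng or random.Random(spec.seed + 2)
    truth = GroundTruth()
    by_term: dict[str, list[TaxonRestriction]] = {}
    for restriction in restrictions:
        by_term.setdefault(restriction.go_id, []).append(restriction)

    active_terms = sorted(t.id for t in graph.terms.values() if not t.is_obsolete)
    merged_alts = sorted(graph._alt_index)
    species = sorted(
        t for t, n in tree.nodes.items() if n.rank == "species"
    ) or sorted(tree.nodes)
    dbs = [f"DB{i + 1}" for i in range(spec.n_databases)]
    codes = list(spec.evidence_mix)
    weights = [max(0.0, spec.evidence_mix[c]) for c in codes]

    def draw_code() -> str:
        return rng.choices(codes, weights=weights)[0]

    anc_cache: dict[str, set[str]] = {}

    def anc(go_id: str) -> set[str]:
        if go_id not in anc_cache:
            anc_cache[go_id] = ancestors(graph, go_id)
        return anc_cache[go_id]

    records: list[AnnotationRecord] = []

    def make_record(db, gene, go_id, code, taxid, qualifier=()) -> AnnotationRecord:
        return AnnotationRecord(
            db=db,
            db_object_id=gene,
            db_object_symbol=gene.lower(),
            qualifier=tuple(qualifier),
            go_id=go_id,
            evidence_code=code,
            taxon_id=taxid,
            assigned_by=db,
            date="20100101",
        )

    # background genes, round-robin over databases, random taxon
    n_planted_records = (
        2 * (spec.planted_redundant_same_ev + spec.planted_redundant_diff_ev)
        + spec.planted_domain_inconsistent
        + spec.planted_taxon_inconsistent
    )
    n_background = spec.n_annotations - n_planted_records
    genes = [
        (dbs[i % len(dbs)], f"G{i + 1:05d}", rng.choice(species))
        for i in range(spec.n_gene_products)
    ]
    gene_terms: dict[tuple[str, str], set[str]] = {}

    def placeable(db: str, gene: str, taxid: int, go_id: str) -> bool:
        existing = gene_terms.setdefault((db, gene), set())
        if go_id in existing:
            return False
        if not _term_consistent(go_id, taxid, tree, lists, by_term):
            return False
        return not (anc(go_id) & existing) and not any(
            go_id in anc(t) for t in existing
        )

    for _ in range(n_background):
        placed = False
        for _ in range(_RETRY_CAP):
            db, gene, taxid = rng.choice(genes)
            go_id = rng.choice(active_terms)
            existing = gene_terms.setdefault((db, gene), set())
            if go_id in existing:
                continue
            if not _term_consistent(go_id, taxid, tree, lists, by_term):
                continue
            closure = anc(go_id)
            if closure & existing or any(go_id in anc(t) for t in existing):
                continue
            qualifier = ("NOT",) if rng.random() < 0.02 else ()
            # occasionally annotate through a retired (merged) accession
            emitted = go_id
            if merged_alts and rng.random() < 0.02:
                alt = rng.choice(merged_alts)
                canonical = graph._alt_index[alt]
                if canonical not in existing and _term_consistent(
                    canonical, taxid, tree, lists, by_term
                ) and not (anc(canonical) & existing) and not any(
                    canonical in anc(t) for t in existing
                ):
                    emitted, closure, go_id = alt, anc(canonical), canonical
                else:
                    continue
            records.append(make_record(db, gene, emitted, draw_code(), taxid, qualifier))
            existing.add(go_id)
            placed = True
            break
        if not placed:
            # rejection sampling exhausted: fall back to an exhaustive scan so
            # that only genuinely infeasible specs are rejected
            for db, gene, taxid in rng.sample(genes, len(genes)):
                options = [t for t in active_terms if placeable(db, gene, taxid, t)]
                if options:
                    go_id = rng.choice(options)
                    records.append(make_record(db, gene, go_id, draw_code(), taxid))
                    gene_terms[(db, gene)].add(go_id)
                    placed = True
                    break
            if not placed:
                raise FixtureSpecError(
                    "could not place a consistent background annotation; "
                    "ontology/taxonomy too constrained for the spec"
                )

    # planted redundant pairs: dedicated gene products with exactly 2 records
    def plant_redundant(i: int, same_evidence: bool) -> None:
        for _ in range(_RETRY_CAP):
            taxid = rng.choice(species)
            desc = rng.choice(active_terms)
            candidates = [
                a
                for a in anc(desc)
                if _term_consistent(a, taxid, tree, lists, by_term)
            ]
            if not candidates or not _term_consistent(desc, taxid, tree, lists, by_term):
                continue
            anc_term = rng.choice(candidates)
            db = rng.choice(dbs)
            gene = f"R{i + 1:05d}"
            if same_evidence:
                code_a = code_d = draw_code()
            else:
                code_a = rng.choice(codes)
                code_d = rng.choice([c for c in codes if c != code_a])
            anc_rec = make_record(db, gene, anc_term, code_a, taxid)
            desc_rec = make_record(db, gene, desc, code_d, taxid)
            records.extend([anc_rec, desc_rec])
            truth.redundant_pairs.append(
                RedundantPair(
                    gene_key=(db, gene),
                    ancestor_annotation=anc_rec,
                    descendant_annotation=desc_rec,
                    same_evidence=same_evidence,
                )
            )
            return
        raise FixtureSpecError("could not plant a redundant pair")

    for i in range(spec.planted_redundant_same_ev):
        plant_redundant(i, True)
    for i in range(spec.planted_redundant_diff_ev):
        plant_redundant(spec.planted_redundant_same_ev + i, False)

    # planted domain-inconsistent records: dedicated single-annotation genes
    prokaryote_species = [s for s in species if superkingdom_of(tree, s) in ("Bacteria", "Archaea")]
    eukaryote_species = [s for s in species if superkingdom_of(tree, s) == "Eukaryota"]
    euk_terms = sorted(lists.eukaryote_only & set(active_terms))
    prok_terms = sorted(lists.prokaryote_only & set(active_terms))
    for i in range(spec.planted_domain_inconsistent):
        use_euk_term = bool(euk_terms and prokaryote_species) and (
            not (prok_terms and eukaryote_species) or i % 2 == 0
        )
        if use_euk_term:
            go_id, taxid = rng.choice(euk_terms), rng.choice(prokaryote_species)
        elif prok_terms and eukaryote_species:
            go_id, taxid = rng.choice(prok_terms), rng.choice(eukaryote_species)
        else:
            raise FixtureSpecError("no feasible domain-inconsistent combination")
        rec = make_record(rng.choice(dbs), f"D{i + 1:05d}", go_id, draw_code(), taxid)
        records.append(rec)
        truth.domain_records.append(rec)

    # planted taxonomy-inconsistent records
    for i in range(spec.planted_taxon_inconsistent):
        placed = False
        for _ in range(_RETRY_CAP):
            restriction = rng.choice(restrictions)
            if restriction.mode == "only_in":
                pool = [
                    s for s in species
                    if not is_descendant(tree, s, restriction.taxon_id)
                ]
            else:
                pool = [
                    s for s in species
                    if is_descendant(tree, s, restriction.taxon_id)
                ]
            pool = [
                s for s in pool
                if _term_consistent(
                    restriction.go_id, s, tree, lists,
                    {k: v for k, v in by_term.items() if k != restriction.go_id},
                )
            ]
            if not pool:
                continue
            rec = make_record(
                rng.choice(dbs), f"T{i + 1:05d}", restriction.go_id,
                draw_code(), rng.choice(pool),
            )
            records.append(rec)
            truth.taxon_records.append(rec)
            placed = True
            break
        if not placed:
            raise FixtureSpecError("could not plant a taxonomy-inconsistent record")

    return AnnotationSet(records=records, source_label=f"synthetic-{spec.seed}"), truth


# -- release pairs --------------------------------------------------------


def generate_release_pair(
    spec: FixtureSpec,
    edits: dict[str, int] | None = None,
    rng: random.Random | None = None,
) -> tuple[OntologyGraph, OntologyGraph, GroundTruth]:
    """An old release plus a new release differing by planted, typed edits.

    ``edits`` maps change type to count; the default plants one edit of each
    of the ten types.  Each edit targets a distinct term, obsoletions and
    merges target leaves so the new release stays structurally valid.
    """
    from .history import CHANGE_TYPES

    rng = rng or random.Random(spec.seed + 3)
    old, truth = generate_ontology(spec, rng)
    if edits is None:
        edits = {t: 1 for t in CHANGE_TYPES}
    unknown = set(edits) - set(CHANGE_TYPES)
    if unknown:
        raise FixtureSpecError(f"unknown change types {sorted(unknown)}")

    new_terms = {go_id: copy.deepcopy(t) for go_id, t in old.terms.items()}
    has_children: set[str] = set()
    for t in old.terms.values():
        for _, parent in t.parents:
            has_children.add(parent)
    active = [t.id for t in old.terms.values() if not t.is_obsolete]
    leaves = [t for t in active if t not in has_children]
    rng.shuffle(leaves)
    non_leaf_pool = [t for t in active if t not in leaves]
    rng.shuffle(non_leaf_pool)
    used: set[str] = set()
    deleted: set[str] = set()
    edit_truth = truth.edits
    next_new_id = 800001
    root_id = _go(1)  # never a leaf, never deleted; safe parent for new terms

    def take(pool: list[str], need_parents: bool = False) -> str:
        while pool:
            go_id = pool.pop()
            if go_id in used:
                continue
            if need_parents and not new_terms[go_id].parents:
                continue
            used.add(go_id)
            return go_id
        raise FixtureSpecError("not enough distinct target terms for the edits")

    def any_active() -> list[str]:
        return [t for t in active if t not in used]

    for change_type in CHANGE_TYPES:
        for _ in range(edits.get(change_type, 0)):
            if change_type == "new_term":
                go_id = _go(next_new_id)
                next_new_id += 1
                new_terms[go_id] = Term(
                    id=go_id, name=f"new term {go_id}",
                    namespace="biological_process",
                    parents=[("is_a", root_id)] if go_id != root_id else [],
                )
                edit_truth.append(("new_term", go_id))
            elif change_type == "new_obsoletion":
                go_id = take(leaves)
                term = new_terms[go_id]
                term.is_obsolete = True
                term.parents = []
                edit_truth.append(("new_obsoletion", go_id))
            elif change_type == "new_term_merge":
                go_id = take(leaves)
                survivors = [t for t in any_active() if t != go_id]
                if not survivors:
                    raise FixtureSpecError("no surviving term available for a merge")
                survivor = rng.choice(survivors)
                used.add(survivor)  # protect the survivor from later deletion
                del new_terms[go_id]
                deleted.add(go_id)
                new_terms[survivor].alt_ids.append(go_id)
                edit_truth.append(("new_term_merge", go_id))
            elif change_type == "term_movement":
                pool = [t for t in any_active() if new_terms[t].parents]
                rng.shuffle(pool)
                go_id = take(pool, need_parents=True)
                term = new_terms[go_id]
                idx = int(go_id.split(":")[1])
                current = {p for _, p in term.parents}
                candidates = [
                    p for p in active
                    if int(p.split(":")[1]) < idx
                    and p not in current
                    and p not in deleted
                ]
                if candidates:
                    term.parents.append(("is_a", rng.choice(candidates)))
                else:
                    # no new parent available: dropping one is still a movement
                    term.parents = term.parents[:-1]
                edit_truth.append(("term_movement", go_id))
            else:
                pool = any_active()
                rng.shuffle(pool)
                go_id = take(pool)
                term = new_terms[go_id]
                if change_type == "term_name_change":
                    term.name = term.name + " (renamed)"
                elif change_type == "new_definition":
                    term.definition = f'"updated definition of {go_id}"'
                elif change_type == "change_comment":
                    term.comment = f"updated comment for {go_id}"
                elif change_type == "change_synonym":
                    term.synonyms.append(f'"synonym of {go_id}" EXACT []')
                elif change_type == "change_category":
                    term.namespace = "molecular_function"
                elif change_type == "change_external_reference":
                    term.xrefs.append(f"XR:{next_new_id:06d}")
                edit_truth.append((change_type, go_id))

    new = OntologyGraph(list(new_terms.values()), version_label="r2")
    return old, new, truth


# -- whole corpora --------------------------------------------------------


@dataclass
class Corpus:
    spec: FixtureSpec
    graph: OntologyGraph
    tree: TaxonomyTree
    lists: DomainTermLists
    restrictions: list[TaxonRestriction]
    annotations: AnnotationSet
    truth: GroundTruth


def generate_corpus(spec: FixtureSpec) -> Corpus:
    """Generate every input the checkers need, deterministically from the seed."""
    rng = random.Random(spec.seed)
    graph, onto_truth = generate_ontology(spec, rng)
    tree = generate_taxonomy(spec, rng)
    lists = generate_domain_lists(spec, graph, rng)
    restrictions = generate_restrictions(spec, graph, tree, lists, rng)
    annotations, truth = generate_annotations(
        spec, graph, tree, lists, restrictions, rng
    )
    truth.merged_ids = onto_truth.merged_ids
    truth.obsolete_ids = onto_truth.obsolete_ids
    return Corpus(spec, graph, tree, lists, restrictions, annotations, truth)


#: Real accessions documented by the quality-control literature, shipped as
#: passthrough labels in the demo domain lists: nucleus and Golgi apparatus
#: (eukaryote-only), cyanelle (eukaryote-only plastid), unidirectional
#: conjugation (prokaryote-only).
REAL_EUKARYOTE_ONLY = ("GO:0005634", "GO:0005794", "GO:0009842")
REAL_PROKARYOTE_ONLY = ("GO:0009291",)


def write_corpus(corpus: Corpus, outdir: str | Path) -> dict[str, str]:
    """Write the corpus as plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "taxonomy": outdir / "taxonomy.tsv",
        "eukaryote_only": outdir / "eukaryote_only.txt",
        "prokaryote_only": outdir / "prokaryote_only.txt",
        "restrictions": outdir / "restrictions.tsv",
        "ground_truth": outdir / "ground_truth.jsonl",
    }
    with open(paths["obo"], "w") as fh:
        write_obo(corpus.graph, fh)
    with open(paths["gaf"], "w") as fh:
        write_gaf(corpus.annotations, fh)
    with open(paths["taxonomy"], "w") as fh:
        write_taxonomy_tsv(corpus.tree, fh)
    with open(paths["eukaryote_only"], "w") as fh:
        for go_id in sorted(corpus.lists.eukaryote_only) + list(REAL_EUKARYOTE_ONLY):
            fh.write(go_id + "\n")
    with open(paths["prokaryote_only"], "w") as fh:
        for go_id in sorted(corpus.lists.prokaryote_only) + list(REAL_PROKARYOTE_ONLY):
            fh.write(go_id + "\n")
    with open(paths["restrictions"], "w") as fh:
        for r in corpus.restrictions:
            fh.write(f"{r.go_id}\t{r.mode}\t{r.taxon_id}\n")
    with open(paths["ground_truth"], "w") as fh:
        for pair in corpus.truth.redundant_pairs:
            fh.write(json.dumps({
                "kind": "redundant",
                "gene_key": list(pair.gene_key),
                "ancestor": asdict(pair.ancestor_annotation),
                "descendant": asdict(pair.descendant_annotation),
                "same_evidence": pair.same_evidence,
            }) + "\n")
        for rec in corpus.truth.domain_records:
            fh.write(json.dumps({"kind": "domain", "record": asdict(rec)}) + "\n")
        for rec in corpus.truth.taxon_records:
            fh.write(json.dumps({"kind": "taxon", "record": asdict(rec)}) + "\n")
        for alt, canonical in corpus.truth.merged_ids.items():
            fh.write(json.dumps({"kind": "merge", "alt": alt, "canonical": canonical}) + "\n")
        for obs in corpus.truth.obsolete_ids:
            fh.write(json.dumps({"kind": "obsoletion", "go_id": obs}) + "\n")
    return {k: str(v) for k, v in paths.items()}
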