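"""Species-usage profiling, enrichment statistics, and attribute correlation.

The enrichment machinery follows standard term-enrichment semantics: gene ->
term membership is propagated to ancestors (true-path rule) before counting,
the upper-tail hypergeometric probability and the one-sided Fisher exact
probability are both reported (they coincide on matched margins), and
Bonferroni correction multiplies by the number of terms actually tested.

Attribute correlation reproduces the structure of the per-database analysis:
each inconsistency count column is correlated (Pearson by default, Spearman
behind a flag) against per-evidence-code usage counts and four global
factors, with databases as observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationSet, EVIDENCE_CODES, GeneKey
from .history import rewrite_annotation_ids
from .inconsistency import (
    Flag,
    RedundantPair,
    correct_domain_and_taxon,
    correct_redundant,
    detect_domain_inconsistent,
    detect_redundant,
    detect_taxon_inconsistent,
)
from .ontology import OntologyGraph, ancestors, resolve_id

ATTRIBUTE_FACTORS = (
    "n_gene_products",
    "n_species",
    "n_go_terms",
    "mean_annotations_per_gene_product",
)

INCONSISTENCY_COLUMNS = ("redundant", "domain", "taxon", "total_inconsistent")


@dataclass
class SpeciesProfile:
    """Usage of one GO term across species.

    ``specificity`` is the fraction of annotations carried by the single most
    frequent species: 1.0 means the term is used by exactly one species (the
    hallmark of a species-specific term), values near 0 mean broad usage.
    """

    go_id: str
    per_taxon_counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_taxon_counts.values())

    @property
    def n_species(self) -> int:
        return len(self.per_taxon_counts)

    @property
    def specificity(self) -> float | None:
        if self.total == 0:
            return None
        return max(self.per_taxon_counts.values()) / self.total

    @property
    def annotations_per_species(self) -> float | None:
        if self.n_species == 0:
            return None
        return self.total / self.n_species


@dataclass
class EnrichmentResult:
    go_id: str
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # population genes carrying the term
    N: int  # population size
    p_hyper: float
    p_fisher: float
    p_bonferroni: float


@dataclass
class CorrelationResult:
    attribute: str
    kind: str
    r: float | None  # None when a column is constant
    n: int


# -- species usage --------------------------------------------------------


def species_profile(
    annotations: AnnotationSet, go_id: str, graph: OntologyGraph | None = None
) -> SpeciesProfile:
    """Per-taxon annotation counts for one term (merged ids resolved first)."""
    target = go_id
    counts: dict[int, int] = {}
    for record in annotations.records:
        term = record.go_id
        if graph is not None:
            res = resolve_id(graph, term)
            if res.status == "merged":
                term = res.canonical
        if term == target:
            counts[record.taxon_id] = counts.get(record.taxon_id, 0) + 1
    return SpeciesProfile(go_id=go_id, per_taxon_counts=counts)


def single_species_terms(annotations: AnnotationSet) -> set[str]:
    """Terms annotated at least once but to exactly one species."""
    taxa_by_term: dict[str, set[int]] = {}
    for record in annotations.records:
        taxa_by_term.setdefault(record.go_id, set()).add(record.taxon_id)
    return {term for term, taxa in taxa_by_term.items() if len(taxa) == 1}


# -- statistics -----------------------------------------------------------


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed through scipy's log-gamma-based survival function, stable for
    population sizes up to ~1e6.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_one_sided(table: Sequence[Sequence[int]]) -> float:
    """One-sided (over-representation) Fisher exact probability on a 2x2 table.

    For the table [[k, n-k], [K-k, N-K-n+k]] this equals
    ``hypergeometric_tail(k, n, K, N)``.  An all-zero table returns 1.0.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if arr.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(arr, alternative="greater")[1])


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """min(1, m * p) elementwise, with m the number of tests."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


# -- enrichment -----------------------------------------------------------


def _gene_term_map(
    annotations: AnnotationSet, graph: OntologyGraph
) -> dict[GeneKey, set[str]]:
    """Gene -> term sets with true-path propagation to ancestors."""
    mapping: dict[GeneKey, set[str]] = {}
    closure_cache: dict[str, set[str]] = {}
    for record in annotations.effective():
        # only primary accessions count: stale merged ids contribute nothing
        # unless the correction pass has rewritten them first
        if resolve_id(graph, record.go_id).status != "primary":
            continue
        term = record.go_id
        if term not in closure_cache:
            closure_cache[term] = {term} | ancestors(graph, term)
        mapping.setdefault(record.gene_key, set()).update(closure_cache[term])
    return mapping


def enrich(
    study: set[GeneKey],
    population: set[GeneKey],
    annotations: AnnotationSet,
    graph: OntologyGraph,
    correct_first: bool = False,
    tree=None,
    domain_lists=None,
    restrictions=None,
) -> list[EnrichmentResult]:
    """Term over-representation in a study set against a population.

    With ``correct_first`` the annotation set is passed through stale-ID
    rewriting, same-evidence redundancy removal, and (when a taxonomy plus
    lists/restrictions are supplied) domain/taxon correction before counting.
    Results cover every term with at least one study hit; Bonferroni m is the
    number of terms tested.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    if correct_first:
        annotations, _ = rewrite_annotation_ids(annotations, graph)
        pairs = detect_redundant(graph, annotations)
        annotations, _ = correct_redundant(pairs, annotations)
        if tree is not None:
            flags: list[Flag] = []
            if domain_lists is not None:
                flags += detect_domain_inconsistent(domain_lists, tree, annotations)
            if restrictions is not None:
                flags += detect_taxon_inconsistent(restrictions, tree, annotations)
            annotations, _ = correct_domain_and_taxon(flags, annotations)
    gene_terms = _gene_term_map(annotations, graph)
    N = len(population)
    n = len(study)
    pop_count: dict[str, int] = {}
    study_count: dict[str, int] = {}
    for gene in population:
        for term in gene_terms.get(gene, ()):
            pop_count[term] = pop_count.get(term, 0) + 1
            if gene in study:
                study_count[term] = study_count.get(term, 0) + 1
    tested = sorted(study_count)
    p_hypers = []
    results = []
    for term in tested:
        k, K = study_count[term], pop_count[term]
        p_h = hypergeometric_tail(k, n, K, N)
        p_f = fisher_one_sided([[k, n - k], [K - k, N - K - n + k]])
        p_hypers.append(p_h)
        results.append(
            EnrichmentResult(
                go_id=term, k=k, n=n, K=K, N=N,
                p_hyper=p_h, p_fisher=p_f, p_bonferroni=math.nan,
            )
        )
    for result, p_adj in zip(results, bonferroni(p_hypers)):
        result.p_bonferroni = p_adj
    return results


# -- attribute table and correlation --------------------------------------


def build_attribute_table(
    annotations: AnnotationSet,
    pairs: Sequence[RedundantPair],
    domain_flags: Sequence[Flag],
    taxon_flags: Sequence[Flag],
) -> pd.DataFrame:
    """One row per source database: evidence-code usage counts, the four
    global factors, and the per-kind inconsistency counts (annotation level,
    ancestor-side convention for redundancy)."""
    codes = sorted(EVIDENCE_CODES)
    rows: dict[str, dict[str, float]] = {}

    def row(db: str) -> dict[str, float]:
        if db not in rows:
            rows[db] = {c: 0 for c in codes}
            rows[db].update({f: 0 for f in ATTRIBUTE_FACTORS})
            rows[db].update({k: 0 for k in INCONSISTENCY_COLUMNS})
        return rows[db]

    per_db_genes: dict[str, set] = {}
    per_db_taxa: dict[str, set] = {}
    per_db_terms: dict[str, set] = {}
    per_db_total: dict[str, int] = {}
    for r in annotations.records:
        row(r.db)[r.evidence_code] += 1
        per_db_genes.setdefault(r.db, set()).add(r.gene_key)
        per_db_taxa.setdefault(r.db, set()).add(r.taxon_id)
        per_db_terms.setdefault(r.db, set()).add(r.go_id)
        per_db_total[r.db] = per_db_total.get(r.db, 0) + 1
    for db in rows:
        rows[db]["n_gene_products"] = len(per_db_genes.get(db, ()))
        rows[db]["n_species"] = len(per_db_taxa.get(db, ()))
        rows[db]["n_go_terms"] = len(per_db_terms.get(db, ()))
        total = per_db_total.get(db, 0)
        n_gp = rows[db]["n_gene_products"]
        rows[db]["mean_annotations_per_gene_product"] = total / n_gp if n_gp else 0.0

    redundant_records = {p.ancestor_annotation for p in pairs}
    for rec in redundant_records:
        row(rec.db)["redundant"] += 1
    for flag in domain_flags:
        row(flag.record.db)["domain"] += 1
    for flag in taxon_flags:
        row(flag.record.db)["taxon"] += 1
    for db in rows:
        rows[db]["total_inconsistent"] = (
            rows[db]["redundant"] + rows[db]["domain"] + rows[db]["taxon"]
        )
    frame = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    frame.index.name = "database"
    return frame


def correlate_attributes(
    table: pd.DataFrame, method: str = "pearson"
) -> list[CorrelationResult]:
    """Correlate each inconsistency column against each attribute column.

    Databases are the observations.  A constant column yields ``r=None``
    (reported as not-available) rather than a spurious coefficient.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(table) < 3:
        raise ValueError("need at least 3 database rows for correlation")
    attr_cols = [
        c for c in table.columns if c not in INCONSISTENCY_COLUMNS
    ]
    out: list[CorrelationResult] = []
    for kind in INCONSISTENCY_COLUMNS:
        if kind not in table.columns:
            continue
        y = table[kind].to_numpy(dtype=float)
        for attr in attr_cols:
            x = table[attr].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r: float | None = None
            elif method == "pearson":
                r = float(stats.pearsonr(x, y)[0])
            else:
                r = float(stats.spearmanr(x, y)[0])
            out.append(CorrelationResult(attribute=attr, kind=kind, r=r, n=len(x)))
    return out
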