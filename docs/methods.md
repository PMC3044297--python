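# Methods

## The model

GO is treated as a directed acyclic graph over terms, with typed parent
edges. Ancestry — and therefore redundancy — is defined over the `is_a` and
`part_of` relations by default, following the true-path reading that an
annotation to a term implicitly annotates all its generalizations and the
wholes it is part of. Other relationship types (`regulates`, …) are parsed
and stored but excluded from ancestry unless a caller opts in, because
propagating annotations across them is not sound. Obsolete terms remain in
the graph (resolution and history need them) but have no parents and always
yield an empty ancestor set.

A *redundant pair* is an ordered pair of same-gene-product annotations
(ancestor-side, descendant-side) where the ancestor-side term is a proper
ancestor of the descendant-side term. Proper ancestry means annotating the
same term twice with different evidence is a duplicate, not a redundancy.
Evidence agreement is tracked per pair: same-evidence pairs are correctable
(the ancestor record adds nothing), different-evidence pairs are reported
but retained by the default correction policy, since an experimentally
supported parent alongside a computationally predicted child is legitimate
dual support, not an error.

The *biological-domain* rule flags a eukaryote-only term on a gene product
whose superkingdom is Bacteria or Archaea, and a prokaryote-only term on a
Eukaryota gene product. Organisms with no superkingdom-ranked ancestor
(viruses, unclassified material) are classified `other` and never flagged —
a deliberately conservative choice, since the two curated lists only assert
membership in one biological domain, not anything about viruses.

The *taxonomy-restriction* rule evaluates `only_in` / `never_in` records
against the annotated species' lineage. The descendant test is inclusive (a
taxon satisfies a restriction to itself), which species-level restrictions
require. Restrictions apply to the annotated term itself by default;
`inherit=True` additionally applies restrictions found on any ancestor of
the term. Both behaviors are exposed because restriction files in the wild
differ on whether descent along the hierarchy is already materialized.

## Counting convention

Summary reports count at three levels — gene products, annotations, terms —
per source database and in total. For redundancy the *ancestor-side* record
of each pair is the redundant annotation: annotation-level counts are
distinct ancestor-side records, term-level counts are distinct ancestor-side
terms. The rationale: under the true-path rule the ancestor annotation is
the information-free member of the pair, and it is also the record the
corrector removes, so detection counts and correction counts agree. A
same-evidence subcount accompanies every redundancy count.

## Correction

Correction is removal-based. `drop_ancestor_same_evidence` (default)
removes the ancestor-side record of every same-evidence pair;
`drop_ancestor_all` removes every ancestor-side record. One pass reaches a
fixed point: any surviving same-evidence pair would have had its ancestor
removed, a contradiction — re-checking corrected output finds zero
same-evidence pairs, and after `drop_ancestor_all`, zero pairs at all.
Domain/taxon correction simply drops flagged records. No replacement terms
are ever invented: merged accessions are rewritten to their canonical id,
but an obsolete id's `replaced_by`/`consider` entries are suggestions, so
applying them requires an explicit flag and exactly one `replaced_by`
candidate.

Records with a `NOT` qualifier are preserved through I/O but excluded from
all three detectors and from enrichment counting: a negated annotation does
not imply annotation to ancestors, so it can be neither redundant nor
domain/taxon-inconsistent in the senses above.

## Release diffing

Two releases are diffed into ten change types: six monthly-report types
(new term, new obsoletion, term name change, new definition, term merge,
term movement) and four editor-report types (comment, synonym, category,
external reference). `term_movement` is any change of the typed parent set,
including becoming parentless. A term that becomes obsolete or merged emits
*only* its status record: obsoletion necessarily clears the parent set and
merging rewrites identity, so emitting the secondary attribute records would
double-count one editorial act. Simultaneous independent edits (e.g. rename
plus move) emit one record per type. Version labels are opaque strings
ordered by supplied sequence; no date parsing.

## Statistics

Enrichment propagates gene→term membership to all ancestors before
counting, then tests each term with at least one study hit. Only primary
accessions contribute membership: a stale merged id counts nothing unless
the correction pass has rewritten it first — this is precisely the effect
corrected enrichment is meant to expose. `p_hyper` is the upper-tail
hypergeometric probability via scipy's log-gamma implementation (stable to
N ≈ 10⁶); `p_fisher` is the one-sided Fisher exact probability, equal on
matched margins and kept as an independent cross-check; Bonferroni
multiplies by the number of terms actually tested (k ≥ 1), not the ontology
size. Only over-representation is tested.

Attribute correlation is Pearson on raw per-database counts (19
evidence-code usage columns including `NA`, plus gene products, species,
distinct terms, and mean annotations per gene product, against the four
inconsistency-count columns). Pearson on heavy-tailed counts is dominated
by the largest databases — that is the intended reading, since database
scale is one of the hypotheses under test; Spearman is available behind a
flag. A constant column yields "not available" rather than a coefficient.

## The synthetic corpus

The generator emulates the statistical shape of a multi-database annotation
corpus: several source databases, an IEA-dominated evidence mix over
experimental and curated codes, species spread over Bacteria, Archaea,
Eukaryota, and a virus branch (the first two species always cover both
biological domains so domain conflicts are plantable in tiny trees).
Ontologies are random rooted DAGs with parents drawn from earlier terms, so
acyclicity holds by construction; merged accessions and obsolete terms are
planted with recorded ground truth.

Background annotations are consistent by construction: a candidate term
must be ancestry-free against the gene's existing terms in both directions
and must violate neither domain list nor any restriction for the gene's
taxon. Placement uses rejection sampling with a retry cap, falling back to
an exhaustive gene × term scan so that only genuinely infeasible
specifications are rejected (never silently under-planted). Each planted
inconsistency lives on a dedicated gene product — redundant pairs as
exactly two records, domain/taxon plants as exactly one — so every plant
produces exactly one detector hit and precision/recall can be asserted as
1.0. Restriction generation only emits restrictions that at least one
species satisfies and at least one violates, keeping both background
placement and planting feasible.

What a green planted-recovery test does *not* establish: the generator does
not reproduce real GO topology statistics (fan-in distributions, depth
profiles), annotation count skew across databases, or the messiness of real
GAF files (IEA-only databases, qualifier zoo, withdrawn taxa). It
establishes detector correctness against exact ground truth, not
performance characteristics on production-scale inputs.

## Numerical and degenerate-input choices

- Hypergeometric preconditions (0 ≤ K ≤ N, 0 ≤ n ≤ N, 0 ≤ k ≤ min(n, K))
  are hard errors; k = 0 returns exactly 1.0.
- An all-zero Fisher table returns 1.0 by convention.
- A never-annotated term's species-profile specificity is "not available",
  not 0.
- Unknown taxa and unresolvable term accessions are never flagged; they go
  to a skip log so silence never masks an input problem.
- The evidence-code vocabulary is closed (the 18 classic codes plus `NA`);
  an unknown code is a format error rather than a silently accepted label.
- Namespace roots are reported, not enforced: a category change can leave a
  namespace temporarily rootless mid-history, so `namespace_roots` is a
  query rather than a validation.

## Known limitations

- No GPAD/GPI input, no cross-database gene-product identifier unification
  (identity is `(db, db_object_id)`), no OWL.
- Bonferroni is the only multiple-testing correction.
- The differ tracks primary-id identity; it cannot distinguish a
  delete-and-recreate from unrelated edits and logs a warning when a term
  disappears without a merge target.
- Merged/deleted NCBI taxid remapping files are out of scope; annotations
  bearing unknown taxa are reported, not resolved.
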