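"""The three detectors, the removal-based corrections, and the summary counts."""

import pytest

from goqc import (
    AnnotationRecord,
    AnnotationSet,
    DomainTermLists,
    TaxonRestriction,
    correct_domain_and_taxon,
    correct_redundant,
    detect_domain_inconsistent,
    detect_redundant,
    detect_taxon_inconsistent,
    parse_obo,
    read_domain_lists,
    read_restrictions,
    summarize,
)

E_COLI, H_PYLORI, HUMAN, ARCHAEON, PHAGE = 562, 210, 9606, 2287, 10710
EUKARYOTA, BACTERIA = 2759, 2


def rec(gene, go_id, evidence="IEA", taxon=HUMAN, db="DB1", qualifier=()):
    return AnnotationRecord(
        db=db, db_object_id=gene, go_id=go_id,
        evidence_code=evidence, taxon_id=taxon, qualifier=tuple(qualifier),
    )


def aset(*records):
    return AnnotationSet(records=list(records))


class TestRedundant:
    def test_single_annotation_no_pair(self, diamond):
        assert detect_redundant(diamond, aset(rec("g", "GO:0000001"))) == []

    def test_diamond_same_evidence(self, diamond):
        pairs = detect_redundant(
            diamond, aset(rec("g", "GO:0000001", "IEA"), rec("g", "GO:0000004", "IEA"))
        )
        assert len(pairs) == 1
        pair = pairs[0]
        assert pair.ancestor_annotation.go_id == "GO:0000001"
        assert pair.descendant_annotation.go_id == "GO:0000004"
        assert pair.same_evidence

    def test_diamond_different_evidence(self, diamond):
        # experimental support on the parent, electronic on the child
        pairs = detect_redundant(
            diamond, aset(rec("g", "GO:0000001", "IDA"), rec("g", "GO:0000004", "IEA"))
        )
        assert len(pairs) == 1 and not pairs[0].same_evidence

    def test_pairs_require_same_gene_product(self, diamond):
        pairs = detect_redundant(
            diamond, aset(rec("g1", "GO:0000001"), rec("g2", "GO:0000004"))
        )
        assert pairs == []

    def test_duplicate_term_is_not_redundant(self, diamond):
        pairs = detect_redundant(
            diamond, aset(rec("g", "GO:0000004", "IEA"), rec("g", "GO:0000004", "IDA"))
        )
        assert pairs == []

    def test_not_qualified_records_ignored(self, diamond):
        pairs = detect_redundant(
            diamond,
            aset(rec("g", "GO:0000001", qualifier=("NOT",)), rec("g", "GO:0000004")),
        )
        assert pairs == []

    def test_merged_id_resolved_before_ancestry(self, diamond):
        # GO:0000014 is an alt_id of GO:0000004
        pairs = detect_redundant(
            diamond, aset(rec("g", "GO:0000001"), rec("g", "GO:0000014"))
        )
        assert len(pairs) == 1

    def test_unresolvable_terms_only_skip_logged(self, diamond):
        skip_log = []
        pairs = detect_redundant(
            diamond,
            aset(rec("g", "GO:0099999"), rec("g", "GO:0000005")),
            skip_log=skip_log,
        )
        assert pairs == []
        assert len(skip_log) == 2

    def test_cross_namespace_pairs_impossible(self):
        graph = parse_obo(
            "[Term]\nid: GO:0000001\nname: p\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: f\nnamespace: molecular_function\n"
        )
        pairs = detect_redundant(
            graph, aset(rec("g", "GO:0000001"), rec("g", "GO:0000002"))
        )
        assert pairs == []


NUCLEUS, CONJUGATION, GOLGI = "GO:0005634", "GO:0009291", "GO:0005794"


@pytest.fixture
def real_lists():
    return DomainTermLists(
        eukaryote_only={NUCLEUS, GOLGI}, prokaryote_only={CONJUGATION}
    )


class TestDomain:
    def test_bacterial_gene_to_nucleus_flagged(self, real_lists, toy_tree):
        flags = detect_domain_inconsistent(
            real_lists, toy_tree, aset(rec("O24899", NUCLEUS, taxon=H_PYLORI))
        )
        assert len(flags) == 1 and flags[0].kind == "domain"

    def test_human_gene_to_nucleus_consistent(self, real_lists, toy_tree):
        assert detect_domain_inconsistent(
            real_lists, toy_tree, aset(rec("g", NUCLEUS, taxon=HUMAN))
        ) == []

    def test_eukaryote_to_conjugation_flagged(self, real_lists, toy_tree):
        flags = detect_domain_inconsistent(
            real_lists, toy_tree, aset(rec("g", CONJUGATION, taxon=HUMAN))
        )
        assert len(flags) == 1

    def test_archaeon_counts_as_prokaryote(self, real_lists, toy_tree):
        flags = detect_domain_inconsistent(
            real_lists, toy_tree, aset(rec("g", NUCLEUS, taxon=ARCHAEON))
        )
        assert len(flags) == 1

    def test_virus_never_flagged(self, real_lists, toy_tree):
        assert detect_domain_inconsistent(
            real_lists, toy_tree,
            aset(rec("g", NUCLEUS, taxon=PHAGE), rec("g", CONJUGATION, taxon=PHAGE)),
        ) == []

    def test_unknown_taxon_skip_logged_not_flagged(self, real_lists, toy_tree):
        skip_log = []
        flags = detect_domain_inconsistent(
            real_lists, toy_tree, aset(rec("g", NUCLEUS, taxon=424242)),
            skip_log=skip_log,
        )
        assert flags == [] and len(skip_log) == 1

    def test_overlapping_lists_rejected(self):
        with pytest.raises(ValueError, match="both domain lists"):
            DomainTermLists(eukaryote_only={NUCLEUS}, prokaryote_only={NUCLEUS})

    def test_list_file_parsing(self):
        lists = read_domain_lists(
            f"# eukaryote-only\n{NUCLEUS}\n{GOLGI}\n", f"{CONJUGATION}\n"
        )
        assert lists.eukaryote_only == {NUCLEUS, GOLGI}
        assert lists.prokaryote_only == {CONJUGATION}


class TestTaxonRestrictions:
    def test_golgi_only_in_eukaryota_flags_e_coli(self, toy_tree):
        restrictions = [TaxonRestriction(GOLGI, "only_in", EUKARYOTA)]
        flags = detect_taxon_inconsistent(
            restrictions, toy_tree, aset(rec("g", GOLGI, taxon=E_COLI))
        )
        assert len(flags) == 1 and flags[0].kind == "taxon"

    def test_human_satisfies_only_in(self, toy_tree):
        restrictions = [TaxonRestriction(GOLGI, "only_in", EUKARYOTA)]
        assert detect_taxon_inconsistent(
            restrictions, toy_tree, aset(rec("g", GOLGI, taxon=HUMAN))
        ) == []

    def test_never_in_bacteria(self, toy_tree):
        restrictions = [TaxonRestriction(NUCLEUS, "never_in", BACTERIA)]
        assert len(detect_taxon_inconsistent(
            restrictions, toy_tree, aset(rec("g", NUCLEUS, taxon=E_COLI))
        )) == 1
        assert detect_taxon_inconsistent(
            restrictions, toy_tree, aset(rec("g", NUCLEUS, taxon=ARCHAEON))
        ) == []

    def test_restriction_applies_to_term_itself_by_default(self, diamond, toy_tree):
        # restriction on the parent does not flag a child annotation by default
        restrictions = [TaxonRestriction("GO:0000001", "only_in", EUKARYOTA)]
        annotations = aset(rec("g", "GO:0000004", taxon=E_COLI))
        assert detect_taxon_inconsistent(restrictions, toy_tree, annotations) == []
        inherited = detect_taxon_inconsistent(
            restrictions, toy_tree, annotations, graph=diamond, inherit=True
        )
        assert len(inherited) == 1

    def test_restriction_file_parsing(self, toy_tree):
        restrictions = read_restrictions(f"{GOLGI}\tonly_in\t{EUKARYOTA}\n")
        assert restrictions == [TaxonRestriction(GOLGI, "only_in", EUKARYOTA)]

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            TaxonRestriction(GOLGI, "sometimes_in", EUKARYOTA)


class TestCorrectRedundant:
    def test_same_evidence_ancestor_dropped(self, diamond):
        annotations = aset(rec("g", "GO:0000001", "IEA"), rec("g", "GO:0000004", "IEA"))
        pairs = detect_redundant(diamond, annotations)
        corrected, log = correct_redundant(pairs, annotations)
        assert [r.go_id for r in corrected.records] == ["GO:0000004"]
        assert len(log) == 1

    def test_different_evidence_both_kept(self, diamond):
        annotations = aset(rec("g", "GO:0000001", "IDA"), rec("g", "GO:0000004", "IEA"))
        pairs = detect_redundant(diamond, annotations)
        corrected, log = correct_redundant(pairs, annotations)
        assert len(corrected) == 2 and log == []

    def test_chain_only_leaf_survives(self):
        graph = parse_obo(
            "[Term]\nid: GO:0000001\nname: a\n\n"
            "[Term]\nid: GO:0000002\nname: b\nis_a: GO:0000001\n\n"
            "[Term]\nid: GO:0000003\nname: c\nis_a: GO:0000002\n"
        )
        annotations = aset(
            rec("g", "GO:0000001"), rec("g", "GO:0000002"), rec("g", "GO:0000003")
        )
        pairs = detect_redundant(graph, annotations)
        corrected, _ = correct_redundant(pairs, annotations)
        assert [r.go_id for r in corrected.records] == ["GO:0000003"]

    def test_drop_ancestor_all_clears_all_pairs(self, diamond):
        annotations = aset(rec("g", "GO:0000001", "IDA"), rec("g", "GO:0000004", "IEA"))
        pairs = detect_redundant(diamond, annotations)
        corrected, _ = correct_redundant(pairs, annotations, "drop_ancestor_all")
        assert detect_redundant(diamond, corrected) == []

    def test_idempotent(self, diamond):
        annotations = aset(rec("g", "GO:0000001"), rec("g", "GO:0000004"))
        pairs = detect_redundant(diamond, annotations)
        once, _ = correct_redundant(pairs, annotations)
        twice, _ = correct_redundant(pairs, once)
        assert once.records == twice.records

    def test_unknown_policy(self, diamond):
        with pytest.raises(ValueError, match="policy"):
            correct_redundant([], aset(), "delete_everything")


class TestCorrectDomainTaxon:
    def test_no_flags_identity(self):
        annotations = aset(rec("g", NUCLEUS))
        corrected, log = correct_domain_and_taxon([], annotations)
        assert corrected.records == annotations.records and log == []

    def test_flagged_record_removed(self, real_lists, toy_tree):
        bad = rec("O24899", NUCLEUS, taxon=H_PYLORI)
        annotations = aset(bad, rec("g", NUCLEUS, taxon=HUMAN))
        flags = detect_domain_inconsistent(real_lists, toy_tree, annotations)
        corrected, log = correct_domain_and_taxon(flags, annotations)
        assert bad not in corrected.records and len(corrected) == 1
        assert log[0][0] == bad

    def test_mixed_set_counts(self, real_lists, toy_tree):
        records = [
            rec("a", NUCLEUS, taxon=H_PYLORI),
            rec("b", CONJUGATION, taxon=HUMAN),
            rec("c", NUCLEUS, taxon=HUMAN),
            rec("d", "GO:0000001", taxon=E_COLI),
            rec("e", "GO:0000002", taxon=HUMAN),
        ]
        flags = detect_domain_inconsistent(real_lists, toy_tree, aset(*records))
        corrected, _ = correct_domain_and_taxon(flags, aset(*records))
        assert len(flags) == 2 and len(corrected) == 3


class TestSummarize:
    def test_empty_input_all_zero(self):
        report = summarize([], [], [], aset())
        assert report.totals["total"].annotations == 0
        assert report.flagged == []

    def test_shared_ancestor_counting_convention(self, toy_tree):
        # one gene, annotations to A, D1, D2 where A is the common ancestor:
        # two pairs but one distinct redundant (ancestor-side) annotation
        graph = parse_obo(
            "[Term]\nid: GO:0000001\nname: a\n\n"
            "[Term]\nid: GO:0000002\nname: d1\nis_a: GO:0000001\n\n"
            "[Term]\nid: GO:0000003\nname: d2\nis_a: GO:0000001\n"
        )
        annotations = aset(
            rec("g", "GO:0000001"), rec("g", "GO:0000002"), rec("g", "GO:0000003")
        )
        pairs = detect_redundant(graph, annotations)
        assert len(pairs) == 2
        report = summarize(pairs, [], [], annotations)
        counts = report.totals["redundant"]
        assert (counts.gene_products, counts.annotations, counts.terms) == (1, 1, 1)

    def test_two_databases_two_rows_plus_total(self, diamond):
        annotations = aset(
            rec("g1", "GO:0000001", db="DB1"), rec("g1", "GO:0000004", db="DB1"),
            rec("g2", "GO:0000001", db="DB2"), rec("g2", "GO:0000004", db="DB2"),
        )
        pairs = detect_redundant(diamond, annotations)
        report = summarize(pairs, [], [], annotations)
        assert set(report.summary) == {"DB1", "DB2"}
        assert report.totals["redundant"].annotations == 2
        frame = report.to_frame()
        assert (frame["database"] == "TOTAL").sum() == 5

    def test_summary_inequalities(self, diamond, toy_tree, real_lists):
        annotations = aset(
            rec("g", "GO:0000001"), rec("g", "GO:0000004"),
            rec("h", NUCLEUS, taxon=H_PYLORI),
        )
        pairs = detect_redundant(diamond, annotations)
        flags = detect_domain_inconsistent(real_lists, toy_tree, annotations)
        report = summarize(pairs, flags, [], annotations)
        for kinds in list(report.summary.values()) + [report.totals]:
            for counts in kinds.values():
                assert counts.gene_products <= counts.annotations
                assert counts.terms <= counts.annotations
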