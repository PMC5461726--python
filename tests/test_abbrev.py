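"""Abbreviation candidate detection and the D1/D2, G1-G4 keep rules."""

import pytest

import litassoc as la
from litassoc.abbrev import extract_long_form

from conftest import make_document


@pytest.fixture(scope="module")
def als_disease_lexicon():
    return la.refine_lexicon(
        [("ALS", "EFO_0000253"), ("amyotrophic lateral sclerosis", "EFO_0000253")],
        "disease")


def _candidate(short="ALS", long="advanced life support", kind="disease",
               doc_id="PMID1", zone=la.ZoneLabel.ABSTRACT, idx=0):
    return la.AbbrevCandidate(short, long, la.EntityKind(kind), doc_id, zone, idx)


class TestFindCandidates:
    def test_annotated_uppercase_parenthesized_token(self, als_disease_lexicon):
        tlex = la.refine_lexicon([("XYZ1", "P1")], "target")
        doc = make_document(
            abstract="Training covered advanced life support (ALS) procedures.")
        mentions = la.annotate(doc, tlex, als_disease_lexicon)
        (cand,) = la.find_candidates(doc, mentions)
        assert cand.short_form == "ALS"
        assert cand.long_form == "advanced life support"
        assert cand.entity_kind == la.EntityKind.DISEASE

    def test_length_boundary_six_chars_rejected(self, als_disease_lexicon):
        tlex = la.refine_lexicon([("ALSXYZ", "P1")], "target")
        doc = make_document(abstract="A long name thing (ALSXYZ) appeared.")
        mentions = la.annotate(doc, tlex, als_disease_lexicon)
        assert any(m.surface == "ALSXYZ" for m in mentions)
        assert la.find_candidates(doc, mentions) == []

    def test_lowercase_containing_token_rejected(self, als_disease_lexicon):
        tlex = la.refine_lexicon([("p53", "P04637")], "target")
        doc = make_document(abstract="The tumor protein (p53) was mutated.")
        mentions = la.annotate(doc, tlex, als_disease_lexicon)
        assert la.find_candidates(doc, mentions) == []

    def test_unannotated_token_yields_no_candidate(self, als_disease_lexicon):
        tlex = la.refine_lexicon([("XYZ1", "P1")], "target")
        doc = make_document(abstract="The working group (TWG) met weekly.")
        mentions = la.annotate(doc, tlex, als_disease_lexicon)
        assert la.find_candidates(doc, mentions) == []

    def test_invariants_on_emitted_candidates(self, als_disease_lexicon):
        tlex = la.refine_lexicon([("XYZ1", "P1")], "target")
        doc = make_document(
            abstract="Care used advanced life support (ALS). Here too (ALS).")
        mentions = la.annotate(doc, tlex, als_disease_lexicon)
        cands = la.find_candidates(doc, mentions)
        assert len(cands) == 1  # first occurrence defines the candidate
        for c in cands:
            assert len(c.short_form) < 6
            assert not any(ch.islower() for ch in c.short_form)


class TestLongFormExtraction:
    def test_window_trims_to_aligned_long_form(self):
        text = "now from first aid to advanced life support (ALS),"
        assert extract_long_form(text, text.index("(ALS)"), "ALS") == \
            "advanced life support"

    def test_falls_back_to_window_when_no_alignment(self):
        text = "measured in the morning cohort (QQQ) daily"
        got = extract_long_form(text, text.index("(QQQ)"), "QQQ")
        assert got == "in the morning cohort"  # N+1 = 4 words


class TestDiseaseRules:
    def test_dropped_when_no_rule_fires(self, als_disease_lexicon):
        doc = make_document(abstract="Care was advanced life support (ALS) based.")
        d = la.filter_disease_candidate(_candidate(), doc, als_disease_lexicon)
        assert d.kept is False and d.rule_fired == "none"

    def test_d1_lexicon_long_form_present_in_document(self, als_disease_lexicon):
        doc = make_document(
            abstract="Patients had amyotrophic lateral sclerosis. See (ALS) data.")
        d = la.filter_disease_candidate(_candidate(), doc, als_disease_lexicon)
        assert d.kept is True and d.rule_fired == "D1"

    def test_d2_keyword_in_long_form(self, als_disease_lexicon):
        doc = make_document(abstract="Unrelated text.")
        cand = _candidate(long="amyotrophic lateral sclerosis disease-like syndrome")
        d = la.filter_disease_candidate(cand, doc, als_disease_lexicon)
        assert d.kept is True and d.rule_fired == "D2"

    def test_wrong_kind_rejected(self, als_disease_lexicon):
        with pytest.raises(ValueError):
            la.filter_disease_candidate(_candidate(kind="target"),
                                        make_document(), als_disease_lexicon)


@pytest.fixture(scope="module")
def tlex():
    return la.refine_lexicon(
        [("IGF1", "P05019"), ("insulin like growth factor 1", "P05019")],
        "target")


class TestGeneRules:

    def test_g1_body_count_above_three_oa_fulltext(self, tlex):
        doc = make_document(
            open_access=True, abstract="Nothing here.",
            sections=[{"heading": "Results",
                       "text": "IGF1 rose. IGF1 fell. IGF1 varied. IGF1 again."}])
        cand = _candidate(short="IGF1", long="unrelated words", kind="target")
        d = la.filter_gene_candidate(cand, doc, tlex)
        assert d.kept is True and d.rule_fired == "G1"

    def test_g1_needs_more_than_three(self, tlex):
        doc = make_document(
            open_access=True,
            sections=[{"heading": "Results",
                       "text": "IGF1 rose. IGF1 fell. IGF1 varied."}])
        cand = _candidate(short="IGF1", long="unrelated words", kind="target")
        d = la.filter_gene_candidate(cand, doc, tlex)
        assert d.rule_fired != "G1"

    def test_g1_skipped_for_abstract_only_documents(self, tlex):
        doc = make_document(
            open_access=False,
            abstract="IGF1 a. IGF1 b. IGF1 c. IGF1 d. IGF1 e.")
        cand = _candidate(short="IGF1", long="unrelated words", kind="target")
        d = la.filter_gene_candidate(cand, doc, tlex)
        assert d.rule_fired != "G1"

    def test_g2_long_form_matches_lexicon_surface(self, tlex):
        cand = _candidate(short="IGF1", long="Insulin Like Growth Factor 1",
                          kind="target")
        d = la.filter_gene_candidate(cand, make_document(), tlex)
        assert d.kept is True and d.rule_fired == "G2"

    def test_g2_enzyme_list(self, tlex):
        cand = _candidate(short="ADA", long="adenosine deaminase", kind="target")
        d = la.filter_gene_candidate(cand, make_document(), tlex,
                                     enzyme_terms={"adenosine deaminase"})
        assert d.kept is True and d.rule_fired == "G2"

    @pytest.mark.parametrize("long_form", [
        "alkaline phosphatases",          # -ases suffix
        "telomerase",                     # -ase suffix
        "nuclear transcription factor",   # keyword
    ])
    def test_g3_suffix_or_keyword(self, tlex, long_form):
        cand = _candidate(short="ABC", long=long_form, kind="target")
        d = la.filter_gene_candidate(cand, make_document(), tlex)
        assert d.kept is True and d.rule_fired == "G3"

    def _context_doc(self, n_sentences, open_access):
        text = " ".join(
            f"The IGF1 gene mutation was studied in diabetes case {i}."
            for i in range(n_sentences))
        if open_access:
            return make_document(open_access=True, abstract="Filler.",
                                 sections=[{"heading": "Results", "text": text}])
        return make_document(abstract=text)

    def _g4_decision(self, doc, tlex):
        dlex = la.refine_lexicon([("diabetes", "EFO_0000400")], "disease")
        mentions = la.annotate(doc, tlex, dlex)
        cand = _candidate(short="IGF1", long="unrelated words", kind="target")
        return la.filter_gene_candidate(cand, doc, tlex, mentions=mentions)

    def test_g4_threshold_two_for_abstracts(self, tlex):
        assert self._g4_decision(self._context_doc(2, False), tlex).rule_fired == "G4"
        assert self._g4_decision(self._context_doc(1, False), tlex).kept is False

    def test_g4_threshold_three_for_fulltext(self, tlex):
        # 3 qualifying sentences fire G4 but would also fire G1 (>3 body
        # occurrences needs 4); with exactly 3 occurrences G1 stays silent
        assert self._g4_decision(self._context_doc(3, True), tlex).rule_fired == "G4"
        assert self._g4_decision(self._context_doc(2, True), tlex).kept is False

    def test_rule_order_is_reported_but_not_outcome_changing(self, tlex):
        # candidate satisfying G2 and G3: first rule in order is recorded
        cand = _candidate(short="IGF1", long="insulin like growth factor 1",
                          kind="target")
        d = la.filter_gene_candidate(cand, make_document(), tlex)
        assert d.kept is True and d.rule_fired == "G2"


class TestApplyDecisions:
    def _mentions(self):
        return [
            la.Mention("PMID1", la.ZoneLabel.ABSTRACT, 0, (0, 3),
                       la.EntityKind.DISEASE, "EFO_0000253", "ALS"),
            la.Mention("PMID1", la.ZoneLabel.ABSTRACT, 2, (10, 13),
                       la.EntityKind.DISEASE, "EFO_0000253", "ALS"),
            la.Mention("PMID1", la.ZoneLabel.ABSTRACT, 1, (0, 4),
                       la.EntityKind.TARGET, "P05019", "IGF1"),
            la.Mention("PMID2", la.ZoneLabel.ABSTRACT, 0, (5, 8),
                       la.EntityKind.DISEASE, "EFO_0000253", "ALS"),
        ]

    def test_dropped_candidate_removes_all_same_doc_mentions(self):
        decisions = [la.FilterDecision(_candidate(), False, "none")]
        kept = la.apply_decisions(self._mentions(), decisions)
        assert [(m.doc_id, m.surface) for m in kept] == \
            [("PMID1", "IGF1"), ("PMID2", "ALS")]  # other doc untouched

    def test_kept_candidate_changes_nothing(self):
        decisions = [la.FilterDecision(_candidate(), True, "D1")]
        assert la.apply_decisions(self._mentions(), decisions) == self._mentions()

    def test_empty_decisions_identity(self):
        assert la.apply_decisions(self._mentions(), []) == self._mentions()

    def test_output_subset_of_input(self):
        decisions = [la.FilterDecision(_candidate(), False, "none")]
        kept = la.apply_decisions(self._mentions(), decisions)
        assert set(kept) <= set(self._mentions())

    def test_conflicting_decisions_raise(self):
        decisions = [la.FilterDecision(_candidate(), False, "none"),
                     la.FilterDecision(_candidate(), True, "D2")]
        with pytest.raises(ValueError, match="conflicting"):
            la.apply_decisions(self._mentions(), decisions)
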