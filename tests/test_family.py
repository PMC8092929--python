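"""FamilyMember annotator: candidates, patterns, rules, side heuristic."""

import pytest

from fhx.family import (
    ALL_RULES,
    AnnotatorConfig,
    CoreferenceLink,
    RelationLexicon,
    annotate_document,
    assign_family_side,
    build_graph,
    detect_candidates,
    normalize_graph,
)
from fhx.model import FamilyMemberAnnotation as FM
from fhx.preprocess import segment


def first_sentence(text):
    return segment("d", text), segment("d", text).sentences()[0]


def annotations(text, lexicon_mode=11, rules=ALL_RULES):
    doc = segment("d", text)
    cfg = AnnotatorConfig(lexicon_mode=lexicon_mode, rules_enabled=rules)
    return annotate_document(doc, cfg)


class TestCandidates:
    def test_basic_detection(self):
        doc, sent = first_sentence("Her father is 53 with high cholesterol.")
        cands = detect_candidates(sent, RelationLexicon(11))
        assert [c.raw_relation for c in cands] == ["Father"]

    def test_no_candidates(self):
        doc, sent = first_sentence("The weather is nice.")
        assert detect_candidates(sent, RelationLexicon(11)) == []

    def test_restricted_lexicon_drops_generic_words(self):
        doc, sent = first_sentence(
            "She has 4 siblings: two brothers and two sisters.")
        got = [c.raw_relation
               for c in detect_candidates(sent, RelationLexicon(11))]
        assert got == ["Brother", "Sister"]
        full = [c.raw_relation
                for c in detect_candidates(sent, RelationLexicon(15))]
        assert full == ["Sibling", "Brother", "Sister"]

    def test_possessive_yields_base_candidate(self):
        doc, sent = first_sentence("Her mother's sister has arthritis.")
        got = [c.raw_relation
               for c in detect_candidates(sent, RelationLexicon(11))]
        assert got == ["Mother", "Sister"]


class TestGraph:
    def build(self, text, mode=11):
        doc = segment("d", text)
        sent = doc.sentences()[0]
        cands = detect_candidates(sent, RelationLexicon(mode))
        return doc, build_graph((None, sent), cands)

    def test_possessive_pattern_edge(self):
        _, g = self.build("Her mother's sister has arthritis.")
        assert [(h.raw_relation, d.raw_relation) for h, d, _ in g.edges] \
            == [("Mother", "Sister")]

    def test_has_pattern_edge(self):
        _, g = self.build("Her father has a brother with asthma.")
        assert [(h.raw_relation, d.raw_relation) for h, d, _ in g.edges] \
            == [("Father", "Brother")]

    def test_of_pattern_edge_reverses(self):
        _, g = self.build("The sister of her mother has migraines.")
        assert [(h.raw_relation, d.raw_relation) for h, d, _ in g.edges] \
            == [("Mother", "Sister")]

    def test_single_candidate_no_edges(self):
        _, g = self.build("Her father died at 62.")
        assert len(g.vertices) == 1 and g.edges == []

    def test_no_pattern_between_coordinated_candidates(self):
        _, g = self.build("Her sister has a son and a daughter.")
        pairs = [(h.raw_relation, d.raw_relation) for h, d, _ in g.edges]
        assert pairs == [("Sister", "Son")]   # son-daughter pair: no pattern

    def test_coreference_link_adds_cross_sentence_edge(self):
        doc = segment("d", "Mrs. Williams' mother is alive and well. "
                           "She has an older sister.")
        s1, s2 = doc.sentences()
        lex = RelationLexicon(11)
        prev = detect_candidates(s1, lex)
        cur = detect_candidates(s2, lex)
        she = s2.start  # "She" starts the second sentence
        link = CoreferenceLink((she, she + 3), prev[0])
        g = build_graph((s1, s2), cur, prev, [link])
        assert [(h.raw_relation, d.raw_relation) for h, d, _ in g.edges] \
            == [("Mother", "Sister")]
        assert normalize_graph(g, doc) == {FM("Aunt", "Maternal")}


class TestRules:
    def test_mother_sister_worked_example(self):
        assert annotations("Her mother's sister has arthritis.") == \
            {FM("Mother", "NA"), FM("Aunt", "Maternal")}

    def test_uncle_rule_paternal(self):
        assert annotations("Her father has a brother with asthma.") == \
            {FM("Father", "NA"), FM("Uncle", "Paternal")}

    def test_grandparents_rule(self):
        assert annotations("Her father's mother died of cancer.") == \
            {FM("Father", "NA"), FM("Grandmother", "Paternal")}

    def test_sibling_kids_suppressed(self):
        assert annotations("Her sister has a healthy son.") == \
            {FM("Sister", "NA")}

    def test_cousin_rule_via_aunt(self):
        assert annotations("Her maternal aunt's son has asthma.") == \
            {FM("Aunt", "Maternal"), FM("Cousin", "Maternal")}

    def test_grandparent_cousin_suppressed(self):
        assert annotations(
            "Her maternal grandmother's cousin visited.") == \
            {FM("Grandmother", "Maternal")}

    def test_too_distant_chain_suppressed(self):
        # a grandparent's brother is a great-uncle: not a task relation
        assert annotations("Her maternal grandmother's brother was ill.") \
            == {FM("Grandmother", "Maternal")}

    def test_isolated_vertex_keeps_raw_relation(self):
        assert annotations("Her brother is healthy.") == {FM("Brother")}

    def test_disabled_rule_falls_back_to_raw(self):
        rules = ALL_RULES - {"R4"}
        assert annotations("Her sister has a healthy son.", rules=rules) \
            == {FM("Sister", "NA"), FM("Son", "NA")}

    def test_all_rules_disabled_is_raw_baseline(self):
        got = annotations("Her mother's sister has arthritis.",
                          rules=frozenset())
        assert got == {FM("Mother", "NA"), FM("Sister", "NA")}


class TestSideHeuristic:
    def test_last_occurrence_wins(self):
        doc = segment("d", "She has a maternal paternal cousin here.")
        cousin = doc.text.index("cousin")
        assert assign_family_side(cousin, doc) == "Paternal"

    def test_no_cue_gives_na(self):
        doc = segment("d", "Her grandmother reportedly had one miscarriage.")
        assert assign_family_side(doc.text.index("grandmother"), doc) == "NA"

    def test_adjacent_side_word(self):
        assert annotations(
            "Her paternal grandmother reportedly had one miscarriage.") \
            == {FM("Grandmother", "Paternal")}

    def test_cue_is_word_bounded(self):
        doc = segment("d", "Grandmothers everywhere agree.")
        assert assign_family_side(len(doc.text), doc) == "NA"


class TestDocumentLevel:
    def test_consecutive_sentences_without_coref(self):
        got = annotations("Her mother is healthy at age 63. "
                          "Her father died at age 48 of COPD.")
        assert got == {FM("Mother", "NA"), FM("Father", "NA")}

    def test_duplicate_mentions_collapse(self):
        got = annotations("Her mother is well. Her mother has asthma. "
                          "Her mother smokes.")
        assert got == {FM("Mother", "NA")}

    def test_invalid_paragraph_is_skipped(self):
        class RejectAll:
            def predict_valid(self, prev_text, text):
                return 0.0, False

        doc = segment("d", "Her mother has asthma.")
        cfg = AnnotatorConfig()
        assert annotate_document(doc, cfg, paragraph_filter=RejectAll()) \
            == set()

    def test_filter_only_removes_annotations(self):
        class RejectSecond:
            def __init__(self):
                self.calls = 0

            def predict_valid(self, prev_text, text):
                self.calls += 1
                return (0.9, True) if self.calls == 1 else (0.1, False)

        text = "Her mother has asthma.\n\nHer father has copd."
        doc = segment("d", text)
        unfiltered = annotate_document(doc, AnnotatorConfig())
        filtered = annotate_document(doc, AnnotatorConfig(),
                                     paragraph_filter=RejectSecond())
        assert filtered <= unfiltered
        assert filtered == {FM("Mother", "NA")}

    def test_first_degree_always_side_na(self):
        got = annotations("Her paternal grandfather is ill. Her father "
                          "has asthma. Her brother has copd.")
        for ann in got:
            if ann.relative in ("Father", "Brother"):
                assert ann.side == "NA"

    def test_excluded_relations_never_output(self):
        text = ("Her niece has asthma. His nephew is well. Her spouse "
                "has copd. Her mother's sister has lupus.")
        for mode in (11, 15):
            got = annotations(text, lexicon_mode=mode)
            assert all(a.relative not in ("Niece", "Nephew", "Spouse")
                       for a in got)
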