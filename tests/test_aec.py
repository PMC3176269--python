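"""AEC query construction, offline retrieval and Naive Bayes training."""

import math

import pytest

from wsdsumm.aec import (
    AecQuery,
    OfflineSearcher,
    QueryClause,
    aec_disambiguate,
    build_aec_queries,
    collect_training_corpus,
    train_nb,
    usable_query_term,
)
from wsdsumm.datasets import WsdInstance
from wsdsumm.kb import Concept, KnowledgeBase, Relation
from wsdsumm.preprocess import default_stopwords


@pytest.fixture
def repair_kb() -> KnowledgeBase:
    """Two senses of "repair": a surgical procedure and wound healing,
    each with monosemous synonyms and related concepts."""
    concepts = [
        Concept("C0374711", "surgical repair", {"repair"},
                {"Therapeutic or preventive procedure"}),
        Concept("C0043240", "wound healing", {"tissue repair", "repair"},
                {"Organ or tissue function"}),
        Concept("C0543467", "operative procedure", set(),
                {"Therapeutic or preventive procedure"}),
        Concept("C0018563", "healing process", set(),
                {"Organ or tissue function"}),
        # unusable relatives: too long, too short, numeric, stop word
        Concept("C0999991", "x" * 60, {"mg", "123", "the"},
                {"Finding"}),
    ]
    relations = [
        Relation("C0374711", "other_related", "C0543467"),
        Relation("C0043240", "other_related", "C0018563"),
        Relation("C0999991", "other_related", "C0374711"),
    ]
    return KnowledgeBase(concepts, relations)


def test_query_term_filters():
    sw = default_stopwords()
    assert usable_query_term("cold storage", sw)
    assert not usable_query_term("x" * 60, sw)       # > 50 characters
    assert not usable_query_term("mg", sw)           # < 3 characters
    assert not usable_query_term("1234", sw)         # pure number
    assert not usable_query_term("the", sw)          # stop word


def test_build_queries_mix_synonyms_and_conjunctions(repair_kb):
    queries = build_aec_queries(repair_kb, "repair")
    by_cui = {q.cui: q for q in queries}
    assert set(by_cui) == {"C0374711", "C0043240"}

    surgical = by_cui["C0374711"].boolean_expression
    assert '"surgical repair"[tiab]' in surgical
    assert '("repair"[tiab] AND "operative procedure"[tiab])' in surgical
    assert " OR " in surgical
    healing = by_cui["C0043240"].boolean_expression
    assert '"wound healing"[tiab]' in healing
    assert '"tissue repair"[tiab]' in healing
    assert '("repair"[tiab] AND "healing process"[tiab])' in healing
    # every quoted phrase is monosemous in the knowledge base
    for q in queries:
        for clause in q.clauses:
            for phrase in clause.phrases:
                if phrase != "repair":
                    assert repair_kb.is_monosemous(phrase)


def test_unusable_relatives_are_filtered(repair_kb):
    surgical = [q for q in build_aec_queries(repair_kb, "repair")
                if q.cui == "C0374711"][0]
    rendered = surgical.boolean_expression
    assert "x" * 60 not in rendered
    assert '"mg"' not in rendered
    assert '"123"' not in rendered
    assert '"the"' not in rendered


def test_fallback_expression_replaces_quotes_with_parentheses(repair_kb):
    q = [q for q in build_aec_queries(repair_kb, "repair")
         if q.cui == "C0374711"][0]
    assert '"' not in q.fallback_expression
    assert "(surgical repair)[tiab]" in q.fallback_expression


def test_build_queries_requires_ambiguous_term(repair_kb):
    with pytest.raises(ValueError):
        build_aec_queries(repair_kb, "wound healing")


def test_offline_searcher_phrase_vs_fallback_semantics():
    docs = [
        "the repair of tissue",            # words present, not the phrase
        "tissue repair accelerates",       # exact phrase
        "nothing relevant here",
    ]
    searcher = OfflineSearcher(docs)
    q = AecQuery("C1", "repair", (QueryClause(("tissue repair",)),))
    assert searcher.search(q, quoted=True) == ["tissue repair accelerates"]
    assert searcher.search(q, quoted=False) == [
        "the repair of tissue", "tissue repair accelerates",
    ]


def test_collect_corpus_uses_fallback_and_caps_limit():
    docs = [f"alpha beta doc{i}" for i in range(5)] + ["gamma delta"]
    searcher = OfflineSearcher(docs)
    # phrase "beta alpha" never occurs contiguously -> fallback matches 5
    q = AecQuery("C1", "t", (QueryClause(("beta alpha",)),))
    corpus = collect_training_corpus([q], searcher, limit=3)
    assert len(corpus) == 3
    assert all(label == "C1" for _, label in corpus)
    assert [doc for doc, _ in corpus] == docs[:3]  # searcher order


def test_collect_corpus_empty_query_flagged(caplog):
    searcher = OfflineSearcher(["some doc"])
    empty = AecQuery("C9", "t", ())
    with caplog.at_level("WARNING"):
        corpus = collect_training_corpus([empty], searcher)
    assert corpus == []
    assert "untrainable" in caplog.text


def test_nb_model_normalization_invariants():
    corpus = [("aa aa bb", "C1"), ("bb cc", "C2")]
    model = train_nb(corpus)
    assert sum(math.exp(v) for v in model.class_log_priors.values()) == \
        pytest.approx(1.0, abs=1e-9)
    for cui in model.classes:
        row = sum(
            math.exp(model.word_log_likelihoods[(cui, w)])
            for w in model.vocabulary
        )
        assert row == pytest.approx(1.0, abs=1e-9)


def test_nb_matches_hand_computed_posteriors():
    """Add-one smoothing oracle computed by hand:
    class C1 counts {aa:2, bb:1}, class C2 counts {bb:1, cc:1}, V=3."""
    corpus = [("aa aa bb", "C1"), ("bb cc", "C2")]
    model = train_nb(corpus)
    assert math.exp(model.word_log_likelihoods[("C1", "aa")]) == \
        pytest.approx(3 / 6)
    assert math.exp(model.word_log_likelihoods[("C2", "cc")]) == \
        pytest.approx(2 / 5)
    inst = WsdInstance("t", "aa bb", frozenset({"C1", "C2"}))
    assert aec_disambiguate(model, inst) == "C1"      # 1/12 vs 1/25
    inst2 = WsdInstance("t", "cc cc", frozenset({"C1", "C2"}))
    assert aec_disambiguate(model, inst2) == "C2"     # 1/72 vs 2/25


def test_nb_separable_classes_and_single_doc_recall():
    corpus = [("aa aa aa", "C1"), ("bb bb bb", "C2")]
    model = train_nb(corpus)
    assert aec_disambiguate(
        model, WsdInstance("t", "aa aa", frozenset({"C1", "C2"}))
    ) == "C1"
    assert aec_disambiguate(
        model, WsdInstance("t", "bb bb bb", frozenset({"C1", "C2"}))
    ) == "C2"


def test_untrained_candidate_excluded_with_warning(caplog):
    model = train_nb([("aa", "C1"), ("bb", "C2")])
    inst = WsdInstance("t", "aa", frozenset({"C1", "C3"}))
    with caplog.at_level("WARNING"):
        assert aec_disambiguate(model, inst) == "C1"
    assert "C3" in caplog.text
    with pytest.raises(ValueError):
        aec_disambiguate(model, WsdInstance("t", "aa", frozenset({"C8", "C9"})))
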