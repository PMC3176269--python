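"""Determinism and structural guarantees of the synthetic generators."""

import pytest

from wsdsumm.datasets import shares_semantic_types
from wsdsumm.fixtures import (
    FixtureError,
    FixtureSpec,
    ambiguous_terms,
    confusion_pool,
    generate_corpus,
    generate_jd_model,
    generate_kb,
    generate_search_corpus,
    generate_wsd_dataset,
    private_vocabulary,
    spec_with,
    write_fixtures,
)
from wsdsumm.kb import load_kb_tsv, save_kb_tsv


SPEC = FixtureSpec(seed=11)


@pytest.fixture(scope="module")
def kb():
    return generate_kb(SPEC)


def test_spec_validation():
    with pytest.raises(FixtureError):
        FixtureSpec(n_concepts=0)
    with pytest.raises(FixtureError):
        FixtureSpec(separability=1.5)
    with pytest.raises(FixtureError):
        FixtureSpec(senses_per_term=1)
    with pytest.raises(FixtureError):
        FixtureSpec(n_concepts=10, n_ambiguous_terms=5)  # below minimum


def test_kb_deterministic_and_valid(tmp_path, kb):
    again = generate_kb(SPEC)
    assert again == kb
    save_kb_tsv(kb, tmp_path / "a")
    save_kb_tsv(again, tmp_path / "b")
    for name in ("concepts.tsv", "terms.tsv", "relations.tsv", "st_associations.tsv"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()
    # passes full kb-module integrity validation on reload
    assert load_kb_tsv(tmp_path / "a") == kb


def test_hierarchy_depth_bound(kb):
    assert max(kb.depth(cui) for cui in kb.concepts) <= SPEC.hierarchy_depth
    assert any(kb.depth(cui) == SPEC.hierarchy_depth for cui in kb.concepts)


def test_planted_ambiguity_structure(kb):
    terms = ambiguous_terms(kb)
    assert len(terms) == SPEC.n_ambiguous_terms
    for term, senses in terms.items():
        assert len(senses) == SPEC.senses_per_term
        # distinct type sets -> JDI-eligible
        type_sets = {kb.semantic_types(c) for c in senses}
        assert len(type_sets) == len(senses)
        # decoy: the smallest CUI carries only a generic type
        assert kb.semantic_types(senses[0]) == frozenset({"Quantitative concept"})
        # sense profiles draw on disjoint private vocabularies
        vocabs = [set(private_vocabulary(kb, c)) for c in senses]
        for i, va in enumerate(vocabs):
            for vb in vocabs[i + 1 :]:
                assert not va & vb


def test_shared_type_variant_makes_jdi_blind():
    kb = generate_kb(spec_with(SPEC, shared_semantic_types=True))
    ds = generate_wsd_dataset(kb, spec_with(SPEC, shared_semantic_types=True))
    assert all(shares_semantic_types(kb, inst) for inst in ds)


def test_dataset_contexts_respect_separability(kb):
    pool = set(confusion_pool(SPEC))
    ds1 = generate_wsd_dataset(kb, spec_with(SPEC, separability=1.0))
    for inst in ds1:
        vocab = set(private_vocabulary(kb, inst.gold))
        assert set(inst.context.split()) <= vocab
    ds0 = generate_wsd_dataset(kb, spec_with(SPEC, separability=0.0))
    for inst in ds0:
        assert set(inst.context.split()) <= pool
    assert generate_wsd_dataset(kb, SPEC).instances == \
        generate_wsd_dataset(kb, SPEC).instances  # deterministic


def test_search_corpus_covers_every_sense(kb):
    docs = generate_search_corpus(kb, SPEC)
    for term, senses in ambiguous_terms(kb).items():
        for cui in senses:
            syn = kb.concepts[cui].preferred_name
            matching = [d for d in docs if syn in d.split()]
            assert len(matching) == SPEC.docs_per_concept


def test_jd_model_orthogonal_and_complete(kb):
    jd = generate_jd_model(kb, SPEC)
    assert jd == generate_jd_model(kb, SPEC)  # deterministic dataclass
    all_types = {t for c in kb.concepts.values() for t in c.semantic_types}
    assert set(jd.st_jd_index) == all_types
    # private definition vocabularies never leak across type JDs
    for term, senses in ambiguous_terms(kb).items():
        for cui in senses:
            own_type = next(iter(kb.semantic_types(cui)))
            own_words = set(private_vocabulary(kb, cui))
            for other_type, vec in jd.jd_vectors.items():
                if other_type == f"JD {own_type}":
                    assert own_words <= set(vec)
                else:
                    assert not own_words & set(vec)


def test_corpus_structure_and_determinism(kb):
    docs = generate_corpus(kb, SPEC)
    assert len(docs) == SPEC.n_documents
    again = generate_corpus(kb, SPEC)
    assert [d.sentences for d in again] == [d.sentences for d in docs]
    for doc in docs:
        assert len(doc.sentences) == SPEC.sentences_per_document
        assert len(doc.topic_sentence_indices) == SPEC.planted_topic_size
        # the gold sense is never the adversarially ordered smallest CUI
        candidates = ambiguous_terms(kb)[doc.ambiguous_term]
        assert doc.gold_cui != min(candidates)
        assert doc.gold_cui in candidates
        # reference is the topic sentences in document order
        expected = " ".join(
            doc.sentences[i] for i in doc.topic_sentence_indices
        )
        assert doc.reference == expected
        # topic sentences mention the ambiguous term
        for i in doc.topic_sentence_indices:
            assert doc.ambiguous_term in doc.sentences[i].split()


def test_zero_topic_size_yields_no_documents(kb):
    assert generate_corpus(kb, spec_with(SPEC, planted_topic_size=0)) == []


def test_write_fixtures_outputs_all_artifacts(tmp_path):
    spec = spec_with(SPEC, n_documents=2, instances_per_term=3)
    paths = write_fixtures(spec, tmp_path)
    assert (tmp_path / "kb" / "concepts.tsv").exists()
    assert (tmp_path / "wsd_dataset.tsv").exists()
    assert (tmp_path / "jd_model.json").exists()
    assert (tmp_path / "corpus" / "doc000.txt").exists()
    assert (tmp_path / "corpus" / "meta.json").exists()
    assert list((tmp_path / "search_corpus").glob("*.txt"))
    assert set(paths) == {"kb", "wsd_dataset", "jd_model", "search_corpus", "corpus"}
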