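"""Concept identification, document-graph construction, HVS clustering
and sentence selection."""

import networkx as nx
import pytest

from wsdsumm.kb import Concept, KnowledgeBase, Relation
from wsdsumm.mrd import build_all_profiles
from wsdsumm.summarizer import (
    Cluster,
    PhraseMapping,
    SentenceConcepts,
    SummarizerError,
    build_document_graph,
    build_sentence_graph,
    cluster_concepts,
    common_mapping_agreement,
    identify_concepts,
    make_resolver,
    score_sentences,
    select_sentences,
    sentence_similarity,
    split_sentences,
    summarize,
    SentenceScore,
)


@pytest.fixture
def chain_kb() -> KnowledgeBase:
    """Two four-level chains plus cross relations for graph tests."""
    concepts = [
        Concept("CA", "entity one", set(), {"Finding"}),
        Concept("CB", "group one", set(), {"Finding"}),
        Concept("CC", "family one", set(), {"Finding"}),
        Concept("CD", "leaf one", set(), {"Disease or syndrome"}),
        Concept("CE", "entity two", set(), {"Finding"}),
        Concept("CF", "group two", set(), {"Finding"}),
        Concept("CX", "leaf two", set(), {"Sign or symptom"}),
    ]
    relations = [
        Relation("CA", "is_a", "CB"),
        Relation("CB", "is_a", "CC"),
        Relation("CC", "is_a", "CD"),
        Relation("CE", "is_a", "CF"),
        Relation("CF", "is_a", "CX"),
        Relation("CC", "other_related", "CX"),
    ]
    return KnowledgeBase(
        concepts, relations, [("Disease or syndrome", "Sign or symptom")]
    )


# ---------------------------------------------------------------------
# concept identification
# ---------------------------------------------------------------------

@pytest.fixture
def ambig_kb() -> KnowledgeBase:
    """Ambiguous term whose smallest CUI is the wrong, generic-typed
    sense (adversarial ordering for the first-mapping baseline)."""
    concepts = [
        Concept("C001", "measurement", {"probe"}, {"Temporal concept"},
                ["interval duration clock"]),
        Concept("C002", "gene probe", {"probe"}, {"Disease or syndrome"},
                ["hybridization dna assay marker"]),
        Concept("C003", "scanner", set(), {"Manufactured object"},
                ["imaging device"]),
    ]
    return KnowledgeBase(concepts)


def test_unambiguous_sentences_independent_of_wsd_choice(ambig_kb):
    profiles = build_all_profiles(ambig_kb)
    for method, kwargs in [("first_mapping", {}), ("mrd", {"profiles": profiles})]:
        resolver = make_resolver(ambig_kb, method, **kwargs)
        scs, decisions = identify_concepts(
            ambig_kb, ["the scanner hums"], resolver
        )
        assert scs[0].concepts == {"C003"}
        assert decisions[0].candidates == frozenset({"C003"})


def test_ambiguous_term_gold_under_mrd_wrong_under_first_mapping(ambig_kb):
    sentence = "probe hybridization dna assay"
    mrd_resolver = make_resolver(ambig_kb, "mrd")
    scs_mrd, _ = identify_concepts(ambig_kb, [sentence], mrd_resolver)
    assert scs_mrd[0].concepts == {"C002"}
    fm = make_resolver(ambig_kb, "first_mapping")
    scs_fm, decisions = identify_concepts(ambig_kb, [sentence], fm)
    assert decisions[0].chosen == "C001"
    # the wrong sense is generic-typed, hence filtered entirely
    assert scs_fm[0].concepts == set()


def test_generic_type_filter_drops_concept(ambig_kb):
    resolver = make_resolver(ambig_kb, "first_mapping")
    scs, decisions = identify_concepts(ambig_kb, ["the measurement"], resolver)
    assert decisions[0].chosen == "C001"
    assert scs[0].concepts == set()  # only semantic type is Temporal concept


def test_longest_match_prefers_multiword_phrase(tiny_kb):
    resolver = make_resolver(tiny_kb, "first_mapping")
    _, decisions = identify_concepts(
        tiny_kb, ["the common cold spreads"], resolver
    )
    assert [d.phrase for d in decisions] == ["common cold"]
    assert decisions[0].candidates == frozenset({"CCOLD1"})


def test_precomputed_mappings_are_honoured(tiny_kb):
    resolver = make_resolver(tiny_kb, "first_mapping")
    scs, decisions = identify_concepts(
        tiny_kb,
        ["unrelated text"],
        resolver,
        precomputed_mappings={0: [("cold", {"CCOLD1", "CCOLD2"})]},
    )
    assert decisions[0].chosen == "CCOLD1"
    assert scs[0].concepts == {"CCOLD1"}


# ---------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------

def test_sentence_graph_trims_two_upper_levels(chain_kb):
    g = build_sentence_graph(chain_kb, SentenceConcepts(0, "", {"CD"}))
    assert set(g.nodes) == {"CC", "CD"}
    assert g.has_edge("CC", "CD")
    assert g.nodes["CC"]["depth"] == 3
    assert g.nodes["CD"]["depth"] == 4


def test_sentence_graph_depth_two_concept_vanishes(chain_kb):
    g = build_sentence_graph(chain_kb, SentenceConcepts(0, "", {"CB"}))
    assert g.number_of_nodes() == 0


def test_sentence_graph_merges_shared_ancestor(chain_kb):
    kb = chain_kb
    # add a second child of CC at depth 4 via a sibling concept
    concepts = list(kb.concepts.values()) + [
        Concept("CD2", "leaf one b", set(), {"Finding"})
    ]
    kb2 = KnowledgeBase(
        concepts, kb.relations + [Relation("CC", "is_a", "CD2")],
        kb.st_associations,
    )
    g = build_sentence_graph(kb2, SentenceConcepts(0, "", {"CD", "CD2"}))
    assert set(g.nodes) == {"CC", "CD", "CD2"}
    assert g.degree["CC"] == 2


def test_document_graph_weights_and_salience(chain_kb):
    sg1 = build_sentence_graph(chain_kb, SentenceConcepts(0, "", {"CD"}))
    sg2 = build_sentence_graph(chain_kb, SentenceConcepts(1, "", {"CX"}))
    g = build_document_graph(chain_kb, [sg1, sg2])
    # is_a edge: parent depth 3, child depth 4 -> 0.75
    assert g.edges["CC", "CD"]["weight"] == pytest.approx(0.75)
    # thesaurus relation between in-graph vertices -> weight 1
    assert g.edges["CC", "CX"]["kind"] == "other_related"
    assert g.edges["CC", "CX"]["weight"] == 1.0
    # associated semantic types between leaf vertices -> weight 1
    assert g.edges["CD", "CX"]["kind"] == "associated_with"
    assert g.edges["CD", "CX"]["weight"] == 1.0
    # salience sums incident weights; conservation holds
    assert g.nodes["CD"]["salience"] == pytest.approx(1.75)
    total_salience = sum(d["salience"] for _, d in g.nodes(data=True))
    total_weight = sum(d["weight"] for _, _, d in g.edges(data=True))
    assert total_salience == pytest.approx(2 * total_weight)
    assert all(0 <= d["weight"] <= 1 for _, _, d in g.edges(data=True))


def test_isolated_vertex_salience_zero(chain_kb):
    kb = KnowledgeBase(
        [
            Concept("CA", "a", set(), {"Finding"}),
            Concept("CB", "b", set(), {"Finding"}),
            Concept("CC", "c", set(), {"Finding"}),
        ],
        [Relation("CA", "is_a", "CB"), Relation("CB", "is_a", "CC")],
    )
    g = build_document_graph(
        kb, [build_sentence_graph(kb, SentenceConcepts(0, "", {"CC"}))]
    )
    assert g.nodes["CC"]["salience"] == 0.0


# ---------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------

def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


def test_two_disconnected_triangles_make_two_clusters():
    g = weighted_graph(
        [("a1", "a2", 1), ("a2", "a3", 1), ("a1", "a3", 1), ("a1", "p1", 1),
         ("b1", "b2", 1), ("b2", "b3", 1), ("b1", "b3", 1), ("b1", "p2", 1)]
    )
    clusters = cluster_concepts(g, hub_fraction=0.25)  # 2 hubs: a1, b1
    assert len(clusters) == 2
    members = sorted(sorted(c.members) for c in clusters)
    assert members == [["a1", "a2", "a3", "p1"], ["b1", "b2", "b3", "p2"]]


def test_fully_connected_graph_single_cluster():
    g = weighted_graph(
        [(u, v, 1) for u in "abcd" for v in "abcd" if u < v]
    )
    clusters = cluster_concepts(g, hub_fraction=0.25)
    assert len(clusters) == 1
    assert clusters[0].members == {"a", "b", "c", "d"}


def test_singleton_graph_single_self_cluster():
    g = nx.Graph()
    g.add_node("v")
    clusters = cluster_concepts(g)
    assert len(clusters) == 1
    assert clusters[0].hvs == frozenset({"v"})
    assert clusters[0].members == {"v"}


def test_unconnected_vertices_stay_unassigned():
    g = weighted_graph([("a", "b", 1)])
    g.add_node("z")
    clusters = cluster_concepts(g, hub_fraction=0.34)
    assigned = set().union(*(c.members for c in clusters))
    assert "z" not in assigned


def test_cluster_partition_and_hvs_disjointness():
    g = weighted_graph(
        [("a", "b", 1), ("b", "c", 0.5), ("d", "e", 1), ("e", "f", 0.5),
         ("c", "d", 0.25)]
    )
    clusters = cluster_concepts(g, hub_fraction=0.4)
    all_members = [m for c in clusters for m in c.members]
    assert len(all_members) == len(set(all_members))  # partition
    all_hvs = [h for c in clusters for h in c.hvs]
    assert len(all_hvs) == len(set(all_hvs))


# ---------------------------------------------------------------------
# scoring and selection
# ---------------------------------------------------------------------

def sentence_graph_of(nodes):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    return g


def test_non_democratic_votes():
    cluster = Cluster(hvs=frozenset({"h1", "h2"}), members={"h1", "h2", "m1"})
    assert sentence_similarity(sentence_graph_of({"h1", "h2", "m1"}), cluster) == 2.5
    assert sentence_similarity(sentence_graph_of({"x", "y"}), cluster) == 0.0
    assert sentence_similarity(sentence_graph_of({"h1", "h2"}), cluster) == 2.0


def test_score_is_size_adjusted_vote_sum():
    c4 = Cluster(hvs=frozenset({"h1", "h2"}), members={"h1", "h2", "m1", "m2"})
    scores = score_sentences([sentence_graph_of({"h1", "h2"})], [c4])
    assert scores[0].total == pytest.approx(0.5)  # 2 votes / size 4

    c2 = Cluster(hvs=frozenset({"p"}), members={"p", "q"})
    c5 = Cluster(hvs=frozenset({"r", "s"}), members={"r", "s", "t", "u", "v"})
    sg = sentence_graph_of({"p", "r", "s", "t"})  # votes: 1 and 1+1+0.5=2.5
    scores = score_sentences([sg], [c2, c5])
    assert scores[0].per_cluster == [1.0, 2.5]
    assert scores[0].total == pytest.approx(1.0 / 2 + 2.5 / 5)

    empty = sentence_graph_of(set())
    assert score_sentences([empty], [c2])[0].total == 0.0


def test_selection_by_word_budget_and_ties():
    sentences = [f"word one two three {i}" for i in range(10)]  # equal lengths
    scores = [SentenceScore(i, [], float(10 - i)) for i in range(10)]
    assert select_sentences(scores, sentences, compression=0.3) == [0, 1, 2]
    assert select_sentences(scores, sentences, compression=1.0) == list(range(10))
    tied = [SentenceScore(i, [], 1.0) for i in range(10)]
    assert select_sentences(tied, sentences, compression=0.3) == [0, 1, 2]
    assert select_sentences(
        [SentenceScore(0, [], 1.0)], ["only sentence"], compression=0.3
    ) == [0]


def test_summarize_contract_checks(tiny_kb):
    with pytest.raises(SummarizerError):
        summarize([], tiny_kb, wsd="first_mapping")
    with pytest.raises(Exception):
        summarize(["a sentence"], tiny_kb, wsd="jdi")  # no JdModel


def test_split_sentences_modes():
    text = "Cold spreads fast. Vitamin C helps! Does it? Yes."
    assert split_sentences(text) == [
        "Cold spreads fast.", "Vitamin C helps!", "Does it?", "Yes.",
    ]
    assert split_sentences("one\ntwo\n\nthree", one_per_line=True) == [
        "one", "two", "three",
    ]


# ---------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------

def mapping(i, phrase, cands, chosen):
    return PhraseMapping(i, phrase, frozenset(cands), chosen)


def test_common_mapping_agreement_fractions():
    amb = [("p1", {"C1", "C2"}), ("p2", {"C1", "C3"}),
           ("p3", {"C2", "C3"}), ("p4", {"C1", "C2"})]
    a = [mapping(i, p, c, sorted(c)[0]) for i, (p, c) in enumerate(amb)]
    b_same = list(a)
    assert common_mapping_agreement(a, b_same) == 1.0
    b_diff = [mapping(i, p, c, sorted(c)[1]) for i, (p, c) in enumerate(amb)]
    assert common_mapping_agreement(a, b_diff) == 0.0
    b_mixed = list(a[:3]) + [mapping(3, "p4", {"C1", "C2"}, "C2")]
    assert common_mapping_agreement(a, b_mixed) == 0.75


def test_agreement_ignores_unambiguous_and_checks_coverage():
    a = [mapping(0, "p", {"C1"}, "C1"), mapping(0, "q", {"C1", "C2"}, "C1")]
    b = [mapping(0, "p", {"C1"}, "C1"), mapping(0, "q", {"C1", "C2"}, "C2")]
    assert common_mapping_agreement(a, b) == 0.0  # singleton ignored
    with pytest.raises(SummarizerError):
        common_mapping_agreement(a, b[:1])
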