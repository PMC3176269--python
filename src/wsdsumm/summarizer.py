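"""Graph-based extractive summarization over a concept knowledge base.

The pipeline follows four steps:

1. *Concept identification* — each sentence is mapped onto knowledge-base
   concepts by greedy longest-match dictionary lookup (standing in for a
   MetaMap-style mapper, which likewise emits candidate CUI sets per
   phrase).  Ambiguous phrases are resolved by a pluggable WSD method
   (MRD, AEC, JDI) or by the no-WSD ``first_mapping`` baseline; concepts
   whose every semantic type is "too generic" are discarded.
2. *Document representation* — each sentence's concepts are extended
   with their full hypernym chains and merged into a sentence graph; the
   two most abstract hierarchy levels are trimmed.  Sentence graphs are
   merged into a document graph, enriched with ``other_related`` edges
   from the thesaurus and ``associated_with`` edges (between leaf
   vertices with associated semantic types) from the type network.
   An is_a edge weighs depth(parent)/depth(child); all other edges
   weigh 1.
3. *Topic recognition* — vertex salience is the summed weight of
   incident edges; the top-salience vertices become hubs, connected hub
   components form hub vertex sets (HVS), and remaining vertices join
   the cluster they are most connected to.
4. *Sentence selection* — non-democratic voting: a sentence vertex gives
   a cluster 1 vote if it is in the cluster's HVS, 0.5 if it is a
   non-HVS member, 0 otherwise; a sentence's score sums its per-cluster
   similarity divided by cluster size.  Sentences are taken by
   descending score until the summary reaches the compression target.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .aec import DocumentSearcher, aec_disambiguate, build_aec_queries, \
    collect_training_corpus, train_nb
from .datasets import ABSTAIN, UndefinedMetricError, WsdInstance
from .jdi import JdModel, jdi_disambiguate
from .kb import KnowledgeBase
from .mrd import ConceptProfile, build_all_profiles, mrd_disambiguate
from .preprocess import tokenize

#: Semantic types regarded as too broad to contribute to summarization.
GENERIC_SEMANTIC_TYPES = frozenset(
    {
        "quantitative concept",
        "qualitative concept",
        "temporal concept",
        "functional concept",
        "idea or concept",
        "intellectual product",
        "mental process",
        "spatial concept",
        "language",
    }
)

WSD_METHODS = ("mrd", "aec", "jdi", "first_mapping")


class SummarizerError(Exception):
    pass


class ConfigurationError(SummarizerError):
    pass


# ---------------------------------------------------------------------
# Sentence handling
# ---------------------------------------------------------------------

_SENTENCE_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9\"'(])")


def split_sentences(text: str, one_per_line: bool = False) -> list[str]:
    """Rule-based sentence segmentation (or one sentence per line)."""
    if one_per_line:
        return [line.strip() for line in text.splitlines() if line.strip()]
    chunks = _SENTENCE_RE.split(text.strip())
    return [c.strip() for c in chunks if c.strip()]


# ---------------------------------------------------------------------
# Step 1: concept identification
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PhraseMapping:
    """One dictionary phrase occurrence and its disambiguation decision."""

    sentence_index: int
    phrase: str
    candidates: frozenset[str]
    chosen: str

    @property
    def ambiguous(self) -> bool:
        return len(self.candidates) > 1


@dataclass
class SentenceConcepts:
    sentence_index: int
    text: str
    concepts: set[str] = field(default_factory=set)


Resolver = Callable[[str, frozenset[str], str], str]


def make_resolver(
    kb: KnowledgeBase,
    method: str,
    profiles: Mapping[str, ConceptProfile] | None = None,
    jd_model: JdModel | None = None,
    searcher: DocumentSearcher | None = None,
    stopwords: frozenset[str] | None = None,
    aec_limit: int = 100,
) -> Resolver:
    """Build the disambiguation callback used by concept identification.

    The callback receives (phrase, candidate CUIs, sentence text) and
    returns the chosen CUI.  ``first_mapping`` takes the smallest CUI —
    the no-WSD baseline.  MRD needs concept ``profiles`` (built from the
    knowledge base if omitted), JDI needs a ``jd_model``, AEC needs a
    document ``searcher`` and trains one Naive Bayes model per ambiguous
    phrase on first sight (cached).  JDI falls back to the first mapping
    when it abstains.
    """
    if method not in WSD_METHODS:
        raise ConfigurationError(f"unknown wsd method {method!r}")

    if method == "first_mapping":
        return lambda phrase, candidates, sentence: min(candidates)

    if method == "mrd":
        prof = profiles if profiles is not None else build_all_profiles(kb, stopwords)

        def resolve_mrd(phrase: str, candidates: frozenset[str], sentence: str) -> str:
            return mrd_disambiguate(set(candidates), sentence, prof, stopwords)

        return resolve_mrd

    if method == "jdi":
        if jd_model is None:
            raise ConfigurationError("jdi requires a JdModel")

        def resolve_jdi(phrase: str, candidates: frozenset[str], sentence: str) -> str:
            inst = WsdInstance(term=phrase, context=sentence,
                               candidates=candidates)
            chosen = jdi_disambiguate(inst, kb, jd_model, stopwords)
            return min(candidates) if chosen == ABSTAIN else chosen

        return resolve_jdi

    # aec
    if searcher is None:
        raise ConfigurationError("aec requires a document searcher")
    cache: dict[str, object] = {}

    def resolve_aec(phrase: str, candidates: frozenset[str], sentence: str) -> str:
        if phrase not in cache:
            queries = build_aec_queries(kb, phrase, stopwords)
            corpus = collect_training_corpus(queries, searcher, limit=aec_limit)
            cache[phrase] = train_nb(corpus, stopwords) if corpus else None
        model = cache[phrase]
        if model is None:
            return min(candidates)
        inst = WsdInstance(term=phrase, context=sentence, candidates=candidates)
        try:
            return aec_disambiguate(model, inst, stopwords)  # type: ignore[arg-type]
        except ValueError:
            return min(candidates)

    return resolve_aec


def _match_phrases(kb: KnowledgeBase, sentence: str) -> list[tuple[str, frozenset[str]]]:
    """Greedy longest-match dictionary lookup, no overlaps."""
    tokens = tokenize(sentence)
    if not tokens:
        return []
    max_len = max((len(key.split()) for key in kb.term_index), default=1)
    matches: list[tuple[str, frozenset[str]]] = []
    i = 0
    while i < len(tokens):
        found = False
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            phrase = " ".join(tokens[i : i + length])
            cuis = kb.term_index.get(phrase)
            if cuis:
                matches.append((phrase, frozenset(cuis)))
                i += length
                found = True
                break
        if not found:
            i += 1
    return matches


def _passes_type_filter(
    kb: KnowledgeBase, cui: str, generic_types: frozenset[str]
) -> bool:
    types = {t.lower() for t in kb.semantic_types(cui)}
    return not types <= generic_types


def identify_concepts(
    kb: KnowledgeBase,
    sentences: Sequence[str],
    resolver: Resolver,
    generic_types: frozenset[str] = GENERIC_SEMANTIC_TYPES,
    precomputed_mappings: Mapping[int, Sequence[tuple[str, Iterable[str]]]] | None = None,
) -> tuple[list[SentenceConcepts], list[PhraseMapping]]:
    """Map each sentence to disambiguated, type-filtered concepts.

    Candidate CUI sets come from the dictionary longest-match (or from
    ``precomputed_mappings``, e.g. real MetaMap output keyed by sentence
    index).  Singleton candidate sets are accepted directly; larger sets
    go through the resolver with the sentence as context.  Concepts whose
    semantic types are all generic are then dropped.  Returns both the
    per-sentence concept sets and the full list of phrase-level decisions
    (for agreement analysis).
    """
    generic = frozenset(t.lower() for t in generic_types)
    sentence_concepts: list[SentenceConcepts] = []
    decisions: list[PhraseMapping] = []
    for idx, sentence in enumerate(sentences):
        if precomputed_mappings is not None:
            matches = [
                (phrase, frozenset(cands))
                for phrase, cands in precomputed_mappings.get(idx, [])
            ]
        else:
            matches = _match_phrases(kb, sentence)
        concepts: set[str] = set()
        for phrase, candidates in matches:
            if len(candidates) == 1:
                chosen = next(iter(candidates))
            else:
                chosen = resolver(phrase, candidates, sentence)
            decisions.append(
                PhraseMapping(idx, phrase, candidates, chosen)
            )
            if _passes_type_filter(kb, chosen, generic):
                concepts.add(chosen)
        sentence_concepts.append(SentenceConcepts(idx, sentence, concepts))
    return sentence_concepts, decisions


# ---------------------------------------------------------------------
# Step 2: document representation
# ---------------------------------------------------------------------

TRIM_DEPTH = 2  # the two most abstract hierarchy levels are removed


def build_sentence_graph(kb: KnowledgeBase, sc: SentenceConcepts) -> nx.Graph:
    """Union of the full hypernym chains of a sentence's concepts, with
    the two upper hierarchy levels removed.  Vertices keep their depth
    as measured on the untrimmed chain (root depth 1)."""
    g = nx.Graph()
    for cui in sc.concepts:
        chain = kb.hypernym_chain(cui)
        for depth, node in enumerate(chain, start=1):
            if node not in g:
                g.add_node(node, depth=depth)
        for parent, child in zip(chain, chain[1:]):
            g.add_edge(parent, child, kind="is_a")
    shallow = [n for n, d in g.nodes(data="depth") if d <= TRIM_DEPTH]
    g.remove_nodes_from(shallow)
    return g


def _edge_weight(kind: str, depth_u: int, depth_v: int) -> float:
    if kind == "is_a":
        parent_depth, child_depth = sorted((depth_u, depth_v))
        return parent_depth / child_depth
    return 1.0


def build_document_graph(
    kb: KnowledgeBase, sentence_graphs: Sequence[nx.Graph]
) -> nx.Graph:
    """Merge sentence graphs and enrich with thesaurus and type-network
    relations.

    is_a edges weigh depth(parent)/depth(child); ``other_related`` edges
    (concept pairs related in the knowledge base) and ``associated_with``
    edges (leaf-vertex pairs whose semantic types are associated) weigh
    exactly 1.  Each vertex's salience is the sum of its incident edge
    weights.
    """
    if not sentence_graphs:
        raise SummarizerError("at least one sentence graph is required")
    g = nx.Graph()
    for sg in sentence_graphs:
        for node, depth in sg.nodes(data="depth"):
            g.add_node(node, depth=depth)
        for u, v, kind in sg.edges(data="kind"):
            g.add_edge(u, v, kind=kind)

    nodes = sorted(g.nodes)
    for i, u in enumerate(nodes):
        related = kb.other_related(u)
        for v in nodes[i + 1 :]:
            if v in related and not g.has_edge(u, v):
                g.add_edge(u, v, kind="other_related")

    # leaves: vertices that parent no other vertex through an is_a edge
    is_a_parents = {
        u if g.nodes[u]["depth"] < g.nodes[v]["depth"] else v
        for u, v, kind in g.edges(data="kind")
        if kind == "is_a"
    }
    leaves = [n for n in nodes if n not in is_a_parents]
    for i, u in enumerate(leaves):
        types_u = kb.semantic_types(u)
        for v in leaves[i + 1 :]:
            if g.has_edge(u, v):
                continue
            if any(
                kb.types_associated(a, b)
                for a in types_u
                for b in kb.semantic_types(v)
            ):
                g.add_edge(u, v, kind="associated_with")

    for u, v, data in g.edges(data=True):
        data["weight"] = _edge_weight(
            data["kind"], g.nodes[u]["depth"], g.nodes[v]["depth"]
        )
    for node in g.nodes:
        g.nodes[node]["salience"] = sum(
            data["weight"] for _, _, data in g.edges(node, data=True)
        )
    return g


# ---------------------------------------------------------------------
# Step 3: topic recognition
# ---------------------------------------------------------------------

@dataclass
class Cluster:
    """A topic: hub vertex set (centroid) plus all member vertices."""

    hvs: frozenset[str]
    members: set[str]

    def __post_init__(self) -> None:
        if not self.hvs:
            raise SummarizerError("cluster with empty hub vertex set")
        self.members |= set(self.hvs)

    def __len__(self) -> int:
        return len(self.members)


def cluster_concepts(g: nx.Graph, hub_fraction: float = 0.1) -> list[Cluster]:
    """Degree-based clustering around hub vertex sets.

    The ``max(1, ceil(hub_fraction * |V|))`` highest-salience vertices
    (ties toward the smaller CUI) become hubs; connected components of
    the hub-induced subgraph form the HVS centroids.  Remaining vertices
    are assigned in descending salience order to the cluster they are
    most connected to (summed edge weight to current members, membership
    updated as assignment proceeds); vertices with no edge into any
    cluster stay unassigned.
    """
    if not 0.0 < hub_fraction <= 1.0:
        raise ValueError("hub_fraction must be in (0, 1]")
    if g.number_of_nodes() == 0:
        return []
    salience = {
        n: sum(data["weight"] for _, _, data in g.edges(n, data=True))
        for n in g.nodes
    }
    ranked = sorted(g.nodes, key=lambda n: (-salience[n], n))
    n_hubs = max(1, math.ceil(hub_fraction * g.number_of_nodes()))
    hubs = set(ranked[:n_hubs])
    hub_sub = g.subgraph(hubs)
    components = sorted(
        (frozenset(comp) for comp in nx.connected_components(hub_sub)),
        key=min,
    )
    clusters = [Cluster(hvs=comp, members=set(comp)) for comp in components]

    for node in ranked:
        if node in hubs:
            continue
        best_idx, best_conn = -1, 0.0
        for idx, cluster in enumerate(clusters):
            conn = sum(
                g.edges[node, member]["weight"]
                for member in cluster.members
                if g.has_edge(node, member)
            )
            if conn > best_conn:
                best_idx, best_conn = idx, conn
        if best_idx >= 0:
            clusters[best_idx].members.add(node)
    return clusters


# ---------------------------------------------------------------------
# Step 4: sentence selection
# ---------------------------------------------------------------------

@dataclass
class SentenceScore:
    sentence_index: int
    per_cluster: list[float]
    total: float


def sentence_similarity(sentence_graph: nx.Graph, cluster: Cluster) -> float:
    """Non-democratic votes of a sentence's vertices for one cluster:
    1 per HVS vertex, 0.5 per non-HVS member, 0 otherwise."""
    votes = 0.0
    for node in sentence_graph.nodes:
        if node in cluster.hvs:
            votes += 1.0
        elif node in cluster.members:
            votes += 0.5
    return votes


def score_sentences(
    sentence_graphs: Sequence[nx.Graph], clusters: Sequence[Cluster]
) -> list[SentenceScore]:
    """Per-sentence score: sum over clusters of similarity divided by
    cluster size."""
    if not clusters:
        raise SummarizerError("score_sentences requires at least one cluster")
    for cluster in clusters:
        if len(cluster) == 0:
            raise SummarizerError("zero-size cluster")
    scores = []
    for idx, sg in enumerate(sentence_graphs):
        votes = [sentence_similarity(sg, cluster) for cluster in clusters]
        total = sum(v / len(c) for v, c in zip(votes, clusters))
        scores.append(SentenceScore(idx, votes, total))
    return scores


def select_sentences(
    scores: Sequence[SentenceScore],
    sentences: Sequence[str],
    compression: float = 0.30,
    size_unit: str = "words",
) -> list[int]:
    """Greedy selection by descending score (ties toward the earlier
    sentence) until the summary first reaches ``compression`` of the body
    size; returns indices in document order."""
    if not 0.0 < compression <= 1.0:
        raise ValueError("compression must be in (0, 1]")
    if size_unit not in ("words", "sentences"):
        raise ValueError("size_unit must be 'words' or 'sentences'")
    if size_unit == "words":
        sizes = [len(tokenize(s)) for s in sentences]
    else:
        sizes = [1] * len(sentences)
    target = compression * sum(sizes)
    order = sorted(scores, key=lambda sc: (-sc.total, sc.sentence_index))
    selected: list[int] = []
    taken = 0.0
    for sc in order:
        if taken >= target:
            break
        selected.append(sc.sentence_index)
        taken += sizes[sc.sentence_index]
    return sorted(selected)


# ---------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------

@dataclass
class SummaryResult:
    sentences: list[str]
    selected: list[int]
    scores: list[SentenceScore]
    clusters: list[Cluster]
    graph: nx.Graph
    sentence_concepts: list[SentenceConcepts]
    mappings: list[PhraseMapping]

    @property
    def summary_text(self) -> str:
        return " ".join(self.sentences[i] for i in self.selected)

    def report(self) -> dict:
        """JSON-serializable inspection report."""
        return {
            "selected": self.selected,
            "scores": [
                {"sentence": sc.sentence_index, "total": sc.total,
                 "votes": sc.per_cluster}
                for sc in self.scores
            ],
            "clusters": [
                {"hvs": sorted(c.hvs), "members": sorted(c.members)}
                for c in self.clusters
            ],
            "concepts": {
                sc.sentence_index: sorted(sc.concepts)
                for sc in self.sentence_concepts
            },
        }


def summarize(
    document: str | Sequence[str],
    kb: KnowledgeBase,
    resolver: Resolver | None = None,
    wsd: str = "first_mapping",
    compression: float = 0.30,
    hub_fraction: float = 0.1,
    size_unit: str = "words",
    generic_types: frozenset[str] = GENERIC_SEMANTIC_TYPES,
    one_per_line: bool = False,
    precomputed_mappings: Mapping[int, Sequence[tuple[str, Iterable[str]]]] | None = None,
    **resolver_kwargs,
) -> SummaryResult:
    """Run the full four-step pipeline over one document.

    ``document`` is raw text or a pre-split sentence sequence.  Either
    pass a ready ``resolver`` or name a ``wsd`` method and supply its
    requirements through keyword arguments (``profiles``, ``jd_model``,
    ``searcher``, ``stopwords``).
    """
    if isinstance(document, str):
        sentences = split_sentences(document, one_per_line=one_per_line)
    else:
        sentences = list(document)
    if not sentences:
        raise SummarizerError("empty document")
    if resolver is None:
        resolver = make_resolver(kb, wsd, **resolver_kwargs)
    sentence_concepts, mappings = identify_concepts(
        kb, sentences, resolver, generic_types, precomputed_mappings
    )
    sentence_graphs = [build_sentence_graph(kb, sc) for sc in sentence_concepts]
    graph = build_document_graph(kb, sentence_graphs)
    clusters = cluster_concepts(graph, hub_fraction)
    if clusters:
        scores = score_sentences(sentence_graphs, clusters)
    else:
        scores = [SentenceScore(i, [], 0.0) for i in range(len(sentences))]
    selected = select_sentences(scores, sentences, compression, size_unit)
    return SummaryResult(
        sentences=sentences,
        selected=selected,
        scores=scores,
        clusters=clusters,
        graph=graph,
        sentence_concepts=sentence_concepts,
        mappings=mappings,
    )


# ---------------------------------------------------------------------
# Agreement analysis
# ---------------------------------------------------------------------

def common_mapping_agreement(
    mappings_a: Sequence[PhraseMapping],
    mappings_b: Sequence[PhraseMapping],
) -> float:
    """Proportion of ambiguous phrase occurrences on which two WSD
    methods chose the same concept.

    Both mapping lists must cover the same phrase occurrences (same
    sentence indices, phrases and candidate sets, in order).  Only
    occurrences with more than one candidate enter the denominator.
    """
    keys_a = [(m.sentence_index, m.phrase, m.candidates) for m in mappings_a]
    keys_b = [(m.sentence_index, m.phrase, m.candidates) for m in mappings_b]
    if keys_a != keys_b:
        raise SummarizerError("mapping lists cover different phrase occurrences")
    pairs = [
        (a.chosen, b.chosen)
        for a, b in zip(mappings_a, mappings_b)
        if a.ambiguous
    ]
    if not pairs:
        raise UndefinedMetricError("no ambiguous phrase occurrences")
    agree = sum(1 for chosen_a, chosen_b in pairs if chosen_a == chosen_b)
    return agree / len(pairs)
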