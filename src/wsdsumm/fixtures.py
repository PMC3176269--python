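"""Deterministic synthetic data: knowledge bases, WSD datasets, document
corpora and JD models.

Everything here is a pure function of a :class:`FixtureSpec` (including
its seed), so the full pipeline can be exercised and tested without the
licensed UMLS, MetaMap or any network access.  Vocabularies are
integer-coded tokens ("w0017"), which makes sense separability exactly
controllable; the generator trades textual realism for analytic control.

Generated structure
-------------------
* The knowledge base is an ``is_a`` forest of the requested depth.  Each
  ambiguous term ("amb000", ...) is attached to ``senses_per_term``
  concepts at the deepest level.  The *first* (lexicographically
  smallest CUI) sense of every term is a decoy carrying only a generic
  semantic type, so the no-WSD first-mapping baseline resolves
  adversarially; the remaining senses carry distinct dedicated types, so
  type-based disambiguation is well-posed (set
  ``shared_semantic_types=True`` to give all senses one type instead,
  the case where JDI must abstain).  Every non-decoy sense has a sibling
  "partner" concept whose semantic type is associated with the sense's
  type, which yields ``associated_with`` leaf edges inside planted
  topics.
* WSD instance contexts draw each word from the gold sense's private
  definition vocabulary with probability ``separability`` and from a
  shared confusion pool otherwise.
* Summarization documents plant a dominant topic: a sense concept, its
  hypernym parent and its partner sibling, mentioned together in
  ``planted_topic_size`` topic sentences; the remaining sentences
  mention off-topic filler concepts.  The reference summary is the
  topic sentences in document order.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .datasets import WsdDataset, WsdInstance
from .jdi import JdModel
from .kb import Concept, KnowledgeBase, Relation
from .preprocess import preprocess

GENERIC_DECOY_TYPE = "Quantitative concept"
SHARED_SENSE_TYPE = "Disease or syndrome"

_BROAD_TYPES = [
    "Biologic function",
    "Anatomical structure",
    "Organism",
    "Chemical viewed structurally",
    "Finding",
    "Pathologic function",
]


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling every synthetic artifact.

    ``vocabulary_size`` is the number of private vocabulary words per
    concept; ``separability`` is the probability that a context word is
    drawn from the gold sense's vocabulary rather than the confusion
    pool.
    """

    seed: int = 0
    n_concepts: int = 40
    hierarchy_depth: int = 4
    n_ambiguous_terms: int = 4
    senses_per_term: int = 2
    separability: float = 1.0
    n_documents: int = 10
    sentences_per_document: int = 10
    planted_topic_size: int = 3
    vocabulary_size: int = 6
    instances_per_term: int = 25
    context_length: int = 20
    sentence_words: int = 10
    docs_per_concept: int = 5
    words_per_search_doc: int = 12
    confusion_pool_size: int = 100
    shared_semantic_types: bool = False

    def __post_init__(self) -> None:
        counts = {
            "n_concepts": self.n_concepts,
            "hierarchy_depth": self.hierarchy_depth,
            "n_ambiguous_terms": self.n_ambiguous_terms,
            "senses_per_term": self.senses_per_term,
            "n_documents": self.n_documents,
            "sentences_per_document": self.sentences_per_document,
            "vocabulary_size": self.vocabulary_size,
            "instances_per_term": self.instances_per_term,
            "context_length": self.context_length,
            "docs_per_concept": self.docs_per_concept,
        }
        for name, value in counts.items():
            if value < 1:
                raise FixtureError(f"{name} must be positive, got {value}")
        if self.planted_topic_size < 0:
            raise FixtureError("planted_topic_size must be >= 0")
        if not 0.0 <= self.separability <= 1.0:
            raise FixtureError("separability must lie in [0, 1]")
        if self.senses_per_term < 2:
            raise FixtureError("senses_per_term must be >= 2")
        if self.hierarchy_depth < 3:
            raise FixtureError("hierarchy_depth must be >= 3 (upper two levels are trimmed)")
        if self.n_concepts < self.min_concepts:
            raise FixtureError(
                f"n_concepts={self.n_concepts} too small; this spec needs "
                f">= {self.min_concepts}"
            )

    @property
    def min_concepts(self) -> int:
        # 2 roots + 4 second-level + (parent, sense, partner) per sense
        # + one filler (parent, leaf) pair
        return 6 + 3 * self.n_ambiguous_terms * self.senses_per_term + 2


def _cui(i: int) -> str:
    return f"C{i + 1:07d}"


def ambiguous_term(t: int) -> str:
    return f"amb{t:03d}"


def confusion_pool(spec: FixtureSpec) -> list[str]:
    """Tokens guaranteed to occur in no concept's profile sources."""
    return [f"conf{i:04d}" for i in range(spec.confusion_pool_size)]


@dataclass
class _Builder:
    spec: FixtureSpec
    concepts: list[Concept] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)
    associations: list[tuple[str, str]] = field(default_factory=list)
    word_counter: int = 0

    def new_concept(
        self,
        semantic_type: str,
        parent: str | None = None,
        extra_synonyms: set[str] | None = None,
    ) -> str:
        i = len(self.concepts)
        cui = _cui(i)
        words = [
            f"w{self.word_counter + k:04d}" for k in range(self.spec.vocabulary_size)
        ]
        self.word_counter += self.spec.vocabulary_size
        concept = Concept(
            cui=cui,
            preferred_name=f"term{i:04d}",
            synonyms=set(extra_synonyms or ()),
            semantic_types={semantic_type},
            definitions=[" ".join(words)],
        )
        self.concepts.append(concept)
        if parent is not None:
            self.relations.append(Relation(parent, "is_a", cui))
        return cui


def generate_kb(spec: FixtureSpec) -> KnowledgeBase:
    """Random ``is_a`` forest with planted ambiguous terms.

    Deterministic per spec (byte-identical TSV output on re-run).
    """
    rng = random.Random(spec.seed)
    b = _Builder(spec)

    roots = [b.new_concept(_BROAD_TYPES[i % len(_BROAD_TYPES)]) for i in range(2)]
    level2 = [
        b.new_concept(_BROAD_TYPES[(2 + i) % len(_BROAD_TYPES)], parent=roots[i % 2])
        for i in range(4)
    ]

    # attachment level for sense/filler parents sits at depth
    # hierarchy_depth - 2, so senses land exactly at the deepest level
    attach_level = roots if spec.hierarchy_depth == 3 else list(level2)
    for extra_depth in range(4, spec.hierarchy_depth):
        anchor = b.new_concept(
            _BROAD_TYPES[extra_depth % len(_BROAD_TYPES)],
            parent=rng.choice(attach_level),
        )
        attach_level = [anchor]

    # fillers first, so they take the smaller CUIs: under a degraded
    # (no-WSD) graph all saliences tie and the CUI tie-break must not
    # favour planted-topic concepts
    n_fillers = (
        spec.n_concepts
        - len(b.concepts)
        - 3 * spec.n_ambiguous_terms * spec.senses_per_term
    )
    while n_fillers > 0:
        parent = b.new_concept(
            _BROAD_TYPES[len(b.concepts) % len(_BROAD_TYPES)],
            parent=rng.choice(attach_level),
        )
        n_fillers -= 1
        if n_fillers > 0:
            b.new_concept(
                _BROAD_TYPES[len(b.concepts) % len(_BROAD_TYPES)], parent=parent
            )
            n_fillers -= 1

    # ambiguous senses: (parent, sense, partner) triples at the deepest level
    for t in range(spec.n_ambiguous_terms):
        term = ambiguous_term(t)
        for j in range(spec.senses_per_term):
            parent = b.new_concept(
                _BROAD_TYPES[(t + j) % len(_BROAD_TYPES)],
                parent=rng.choice(attach_level),
            )
            if spec.shared_semantic_types:
                sense_type = SHARED_SENSE_TYPE
            elif j == 0:
                sense_type = GENERIC_DECOY_TYPE
            else:
                sense_type = f"Sense type {t}-{j}"
            b.new_concept(sense_type, parent=parent, extra_synonyms={term})
            partner_type = f"Partner type {t}-{j}"
            b.new_concept(partner_type, parent=parent)
            if not spec.shared_semantic_types and j > 0:
                b.associations.append((sense_type, partner_type))

    # a few other_related edges among the broad upper-level concepts;
    # those levels are trimmed from document graphs, so the edges
    # exercise profile construction and round-trip I/O without touching
    # sense separability or planted-topic salience
    eligible = [c.cui for c in b.concepts[: 6 if spec.hierarchy_depth > 3 else 2]]
    n_extra = min(4, len(eligible) // 2)
    existing = {(r.source, r.target) for r in b.relations}
    for _ in range(n_extra):
        u, v = rng.sample(eligible, 2)
        if (u, v) in existing or (v, u) in existing:
            continue
        b.relations.append(Relation(u, "other_related", v))
        existing.add((u, v))

    return KnowledgeBase(b.concepts, b.relations, b.associations)


def _planned_sense_cuis(spec: FixtureSpec) -> dict[str, list[str]]:
    """CUIs the deterministic layout assigns to each ambiguous term's
    senses (decoy first), without building the knowledge base."""
    offset = spec.n_concepts - 3 * spec.n_ambiguous_terms * spec.senses_per_term
    out: dict[str, list[str]] = {}
    idx = offset
    for t in range(spec.n_ambiguous_terms):
        senses = []
        for _ in range(spec.senses_per_term):
            senses.append(_cui(idx + 1))  # parent, sense, partner
            idx += 3
        out[ambiguous_term(t)] = senses
    return out


# ---------------------------------------------------------------------
# Derived views of a generated knowledge base
# ---------------------------------------------------------------------

def ambiguous_terms(kb: KnowledgeBase) -> dict[str, list[str]]:
    """All terms with more than one candidate, with sorted candidates."""
    return {
        term: sorted(cuis)
        for term, cuis in sorted(kb.term_index.items())
        if len(cuis) > 1
    }


def private_vocabulary(kb: KnowledgeBase, cui: str) -> list[str]:
    """A concept's own definition tokens (disjoint across concepts by
    construction)."""
    words: list[str] = []
    for definition in kb.concepts[cui].definitions:
        words.extend(definition.split())
    return words


def monosemous_synonym(kb: KnowledgeBase, cui: str) -> str:
    return kb.concepts[cui].preferred_name


# ---------------------------------------------------------------------
# WSD dataset
# ---------------------------------------------------------------------

def generate_wsd_dataset(kb: KnowledgeBase, spec: FixtureSpec) -> WsdDataset:
    """Instances whose contexts mix gold-profile words (probability
    ``separability``) with confusion-pool words."""
    rng = random.Random(spec.seed + 1)
    pool = confusion_pool(spec)
    instances: list[WsdInstance] = []
    for term, candidates in ambiguous_terms(kb).items():
        for _ in range(spec.instances_per_term):
            gold = rng.choice(candidates)
            vocab = private_vocabulary(kb, gold)
            words = [
                rng.choice(vocab)
                if rng.random() < spec.separability
                else rng.choice(pool)
                for _ in range(spec.context_length)
            ]
            instances.append(
                WsdInstance(
                    term=term,
                    context=" ".join(words),
                    candidates=frozenset(candidates),
                    gold=gold,
                )
            )
    return WsdDataset(
        instances=instances, name=f"synthetic-s{spec.separability:g}"
    )


# ---------------------------------------------------------------------
# Offline search corpus (pseudo-MEDLINE for AEC)
# ---------------------------------------------------------------------

def generate_search_corpus(kb: KnowledgeBase, spec: FixtureSpec) -> list[str]:
    """Documents retrievable by AEC queries: per sense concept,
    ``docs_per_concept`` equal-length documents containing one of its
    monosemous synonyms plus words from its private vocabulary."""
    rng = random.Random(spec.seed + 2)
    docs: list[str] = []
    for term, candidates in ambiguous_terms(kb).items():
        for cui in candidates:
            syn = monosemous_synonym(kb, cui)
            vocab = private_vocabulary(kb, cui)
            for _ in range(spec.docs_per_concept):
                body = rng.choices(vocab, k=spec.words_per_search_doc)
                docs.append(syn + " " + " ".join(body))
    return docs


# ---------------------------------------------------------------------
# JD model
# ---------------------------------------------------------------------

def generate_jd_model(kb: KnowledgeBase, spec: FixtureSpec) -> JdModel:
    """One synthetic journal descriptor per semantic type.

    Each JD's word vector spans the stemmed private vocabularies and
    synonyms of the concepts carrying that type (near-orthogonal across
    types, since private vocabularies are disjoint); the semantic-type
    index is one-hot on the type's own JD.
    """
    types: dict[str, set[str]] = {}
    for cui, concept in sorted(kb.concepts.items()):
        words: set[str] = set()
        for source in kb.concepts[cui].definitions + sorted(concept.synonyms):
            words.update(preprocess(source))
        for st in concept.semantic_types:
            types.setdefault(st, set()).update(words)
    jd_vectors = {
        f"JD {st}": {w: round(1.0 / max(1, len(words)), 9) for w in sorted(words)}
        for st, words in types.items()
    }
    # sparse score vectors: JD ids absent from a type's row count as zero
    st_jd_index = {st: {f"JD {st}": 1.0} for st in types}
    return JdModel(jd_vectors=jd_vectors, st_jd_index=st_jd_index)


# ---------------------------------------------------------------------
# Summarization corpus
# ---------------------------------------------------------------------

@dataclass
class SummDocument:
    """One synthetic document with its planted topic and reference."""

    doc_id: str
    sentences: list[str]
    reference: str
    topic_sentence_indices: list[int]
    topic_cuis: list[str]
    ambiguous_term: str
    gold_cui: str

    @property
    def text(self) -> str:
        return "\n".join(self.sentences)


def generate_corpus(kb: KnowledgeBase, spec: FixtureSpec) -> list[SummDocument]:
    """Documents with a planted dominant topic and gold references.

    Each document's topic is one ambiguous term resolved to a gold sense
    that is *not* the smallest candidate CUI (the smallest is the
    generic-typed decoy), so the first-mapping baseline loses the topic
    concept while a correct disambiguator keeps it.  Topic sentences
    mention the ambiguous term, the gold sense's hypernym parent and its
    partner sibling, plus gold vocabulary words; filler sentences
    mention off-topic concepts and confusion words.  With
    ``planted_topic_size=0`` there is no reference summary and no
    documents are produced.
    """
    if spec.planted_topic_size == 0:
        return []
    if spec.hierarchy_depth < 4:
        raise FixtureError(
            "generate_corpus needs hierarchy_depth >= 4 so planted topic "
            "concepts survive hierarchy trimming"
        )
    if spec.planted_topic_size >= spec.sentences_per_document:
        raise FixtureError("planted_topic_size must leave room for filler sentences")
    rng = random.Random(spec.seed + 3)
    terms = ambiguous_terms(kb)
    if not terms:
        raise FixtureError("knowledge base has no ambiguous terms")
    pool = confusion_pool(spec)

    sense_cuis = {c for senses in terms.values() for c in senses}
    partner_of: dict[str, str] = {}
    for senses in terms.values():
        for cui in senses:
            parent = min(kb.parents(cui))
            siblings = sorted(kb.children(parent) - {cui} - sense_cuis)
            if siblings:
                partner_of[cui] = siblings[0]
    # filler leaves: depth-4+ concepts outside every planted topic triple
    topic_adjacent = (
        sense_cuis
        | set(partner_of.values())
        | {min(kb.parents(c)) for c in sense_cuis}
    )
    filler_leaves = sorted(
        cui
        for cui in kb.concepts
        if kb.depth(cui) >= 4 and cui not in topic_adjacent
    )
    if not filler_leaves:
        raise FixtureError("no filler concepts available; increase n_concepts")

    documents: list[SummDocument] = []
    for d in range(spec.n_documents):
        term = rng.choice(sorted(terms))
        candidates = terms[term]
        gold = rng.choice(candidates[1:])  # never the decoy
        parent = min(kb.parents(gold))
        partner = partner_of.get(gold)
        vocab = private_vocabulary(kb, gold)
        topic_cuis = [gold, parent] + ([partner] if partner else [])

        topic_sentences = []
        for _ in range(spec.planted_topic_size):
            mentions = [term, kb.concepts[parent].preferred_name]
            if partner:
                mentions.append(kb.concepts[partner].preferred_name)
            filler_words = rng.choices(
                vocab, k=max(0, spec.sentence_words - len(mentions))
            )
            topic_sentences.append(" ".join(mentions + filler_words))
        filler_sentences = []
        for _ in range(spec.sentences_per_document - spec.planted_topic_size):
            leaf = rng.choice(filler_leaves)
            words = rng.choices(pool, k=max(0, spec.sentence_words - 1))
            filler_sentences.append(
                " ".join([kb.concepts[leaf].preferred_name] + words)
            )

        positions = list(range(spec.sentences_per_document))
        rng.shuffle(positions)
        topic_positions = sorted(positions[: spec.planted_topic_size])
        sentences = [""] * spec.sentences_per_document
        for idx, pos in enumerate(topic_positions):
            sentences[pos] = topic_sentences[idx]
        rest = iter(filler_sentences)
        for pos in range(spec.sentences_per_document):
            if not sentences[pos]:
                sentences[pos] = next(rest)
        documents.append(
            SummDocument(
                doc_id=f"doc{d:03d}",
                sentences=sentences,
                reference=" ".join(sentences[pos] for pos in topic_positions),
                topic_sentence_indices=topic_positions,
                topic_cuis=topic_cuis,
                ambiguous_term=term,
                gold_cui=gold,
            )
        )
    return documents


# ---------------------------------------------------------------------
# Writing fixtures to disk
# ---------------------------------------------------------------------

def write_fixtures(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Generate and persist every artifact; returns written paths."""
    import json

    from .datasets import save_dataset_tsv
    from .kb import save_kb_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kb = generate_kb(spec)
    save_kb_tsv(kb, out / "kb")
    dataset = generate_wsd_dataset(kb, spec)
    save_dataset_tsv(dataset, out / "wsd_dataset.tsv")
    jd = generate_jd_model(kb, spec)
    jd.save_json(out / "jd_model.json")
    search_dir = out / "search_corpus"
    search_dir.mkdir(exist_ok=True)
    for i, doc in enumerate(generate_search_corpus(kb, spec)):
        (search_dir / f"doc{i:04d}.txt").write_text(doc + "\n", "utf-8")
    corpus_dir = out / "corpus"
    corpus_dir.mkdir(exist_ok=True)
    meta = {}
    for doc in generate_corpus(kb, spec):
        (corpus_dir / f"{doc.doc_id}.txt").write_text(doc.text + "\n", "utf-8")
        (corpus_dir / f"{doc.doc_id}.ref.txt").write_text(doc.reference + "\n", "utf-8")
        meta[doc.doc_id] = {
            "topic_sentence_indices": doc.topic_sentence_indices,
            "topic_cuis": doc.topic_cuis,
            "ambiguous_term": doc.ambiguous_term,
            "gold_cui": doc.gold_cui,
        }
    (corpus_dir / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True), "utf-8")
    return {
        "kb": str(out / "kb"),
        "wsd_dataset": str(out / "wsd_dataset.tsv"),
        "jd_model": str(out / "jd_model.json"),
        "search_corpus": str(search_dir),
        "corpus": str(corpus_dir),
    }


def spec_with(spec: FixtureSpec, **overrides) -> FixtureSpec:
    """Convenience: a copy of the spec with fields replaced."""
    return replace(spec, **overrides)
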