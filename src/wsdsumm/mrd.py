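"""Machine Readable Dictionary (MRD) disambiguation.

A relaxation of Lesk's dictionary-overlap idea: each candidate sense of
an ambiguous term gets a *concept profile* — a sparse vector over
stemmed words drawn from the concept's definitions, synonyms and
directly related concepts (siblings excluded).  Word weights are
tf x icf, where the inverted concept frequency discounts words that
recur across many concepts in the knowledge base.  The context of the
ambiguous occurrence is preprocessed into a raw-frequency vector and the
candidate whose profile has the highest cosine similarity to it wins.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

from .kb import KnowledgeBase
from .preprocess import ContextVector, preprocess


@dataclass
class ConceptProfile:
    """tf x icf weighted bag of stemmed words describing one sense."""

    cui: str
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class IcfStats:
    """Corpus-level concept frequencies for the icf weighting.

    ``n_concepts`` is the number of concepts in the knowledge base and
    ``concept_freq[w]`` the number of concepts whose profile sources
    contain the stemmed word ``w``.
    """

    n_concepts: int
    concept_freq: Counter

    def icf(self, word: str) -> float:
        """Smoothed inverse concept frequency, always >= 1."""
        return math.log((1 + self.n_concepts) / (1 + self.concept_freq[word])) + 1.0


def compute_icf_stats(
    kb: KnowledgeBase, stopwords: frozenset[str] | None = None
) -> IcfStats:
    """Count, per stemmed word, how many concepts' sources contain it."""
    freq: Counter = Counter()
    for cui in kb.concepts:
        words = set()
        for source in kb.profile_sources(cui):
            words.update(preprocess(source, stopwords))
        freq.update(words)
    return IcfStats(n_concepts=len(kb.concepts), concept_freq=freq)


def build_concept_profile(
    kb: KnowledgeBase,
    cui: str,
    icf_stats: IcfStats,
    stopwords: frozenset[str] | None = None,
) -> ConceptProfile:
    """Profile weights: term frequency in the sources times icf."""
    tf: Counter = Counter()
    for source in kb.profile_sources(cui):
        tf.update(preprocess(source, stopwords))
    weights = {w: count * icf_stats.icf(w) for w, count in tf.items()}
    return ConceptProfile(cui=cui, weights=weights)


def build_all_profiles(
    kb: KnowledgeBase, stopwords: frozenset[str] | None = None
) -> dict[str, ConceptProfile]:
    """Profiles for every concept, sharing one icf computation."""
    stats = compute_icf_stats(kb, stopwords)
    return {cui: build_concept_profile(kb, cui, stats, stopwords) for cui in kb.concepts}


def cosine(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    """Cosine similarity of two sparse non-negative vectors; 0 if either
    is all-zero."""
    if len(b) < len(a):
        a, b = b, a
    dot = sum(w * b[k] for k, w in a.items() if k in b)
    norm_a = math.sqrt(sum(w * w for w in a.values()))
    norm_b = math.sqrt(sum(w * w for w in b.values()))
    if norm_a == 0.0 or norm_b == 0.0:
        return 0.0
    return dot / (norm_a * norm_b)


def mrd_rank(
    candidates: set[str],
    context: ContextVector,
    profiles: Mapping[str, ConceptProfile],
) -> list[tuple[str, float]]:
    """Candidates with their cosine scores, best first.

    Ties break toward the lexicographically smallest CUI so the ranking
    is deterministic.
    """
    if not candidates:
        raise ValueError("mrd_rank requires at least one candidate")
    scored = [
        (cui, cosine(profiles[cui].weights, context)) for cui in sorted(candidates)
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def mrd_disambiguate(
    candidates: set[str],
    context: str | ContextVector,
    profiles: Mapping[str, ConceptProfile],
    stopwords: frozenset[str] | None = None,
) -> str:
    """Pick the candidate whose profile best matches the context.

    ``context`` may be raw text (preprocessed here) or an already built
    frequency vector.  When every similarity is zero the smallest CUI is
    returned.
    """
    if isinstance(context, str):
        context = preprocess(context, stopwords)
    return mrd_rank(candidates, context, profiles)[0][0]
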