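"""Automatic Extracted Corpus (AEC) disambiguation.

Instead of hand-annotated training data, each candidate sense acquires
a pseudo-labeled corpus: boolean queries built from its *monosemous
relatives* (synonyms and terms of related concepts that map to exactly
one concept) retrieve documents whose titles/abstracts mention those
unambiguous proxies.  Retrieved documents are labeled with the
candidate's CUI and used to train a multinomial Naive Bayes classifier,
which then predicts the sense of new contexts.

Retrieval goes through a small searcher interface: an offline boolean
searcher over a local document collection (used throughout the tests)
and an optional live NCBI E-utilities client with the same contract.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
from sklearn.naive_bayes import MultinomialNB

from .datasets import WsdInstance
from .kb import KnowledgeBase
from .preprocess import normalize_term, preprocess, tokenize

logger = logging.getLogger(__name__)

MAX_TERM_CHARS = 50  # long terms are unlikely to occur verbatim in abstracts
MIN_TERM_CHARS = 3   # very short terms and numbers are almost certainly ambiguous


class RetrievalError(Exception):
    pass


def usable_query_term(term: str, stopwords: frozenset[str]) -> bool:
    """Filter applied to every monosemous relative before it enters a query."""
    norm = normalize_term(term)
    if not norm or len(norm) > MAX_TERM_CHARS or len(norm) < MIN_TERM_CHARS:
        return False
    if re.fullmatch(r"[0-9 ]+", norm):
        return False
    if norm in stopwords:
        return False
    return True


@dataclass(frozen=True)
class QueryClause:
    """Conjunction of phrases; a single phrase is a monosemous synonym,
    a pair is the ambiguous term AND one monosemous related term."""

    phrases: tuple[str, ...]


@dataclass
class AecQuery:
    """Boolean retrieval query for one candidate sense.

    The clauses are joined with OR.  ``expression`` renders the
    E-utilities string with quoted phrases and the ``[tiab]`` field tag;
    the fallback form replaces quotes with parentheses so phrase words
    may occur anywhere in the title or abstract.
    """

    cui: str
    term: str
    clauses: tuple[QueryClause, ...]
    field: str = "[tiab]"

    @property
    def is_empty(self) -> bool:
        return not self.clauses

    def _render(self, quoted: bool) -> str:
        def wrap(phrase: str) -> str:
            body = f'"{phrase}"' if quoted else f"({phrase})"
            return body + self.field

        parts = []
        for clause in self.clauses:
            if len(clause.phrases) == 1:
                parts.append(wrap(clause.phrases[0]))
            else:
                parts.append("(" + " AND ".join(wrap(p) for p in clause.phrases) + ")")
        return " OR ".join(parts)

    @property
    def boolean_expression(self) -> str:
        return self._render(quoted=True)

    @property
    def fallback_expression(self) -> str:
        return self._render(quoted=False)


def monosemous_relatives(
    kb: KnowledgeBase, cui: str, stopwords: frozenset[str]
) -> tuple[list[str], list[str]]:
    """(monosemous synonyms of ``cui``, monosemous terms of related
    concepts), both filtered and sorted for determinism."""
    synonyms = sorted(
        syn for syn in kb.concepts[cui].synonyms
        if kb.is_monosemous(syn) and usable_query_term(syn, stopwords)
    )
    related_cuis = kb.parents(cui) | kb.children(cui) | kb.other_related(cui)
    related_terms = sorted(
        {
            syn
            for rel_cui in related_cuis
            for syn in kb.concepts[rel_cui].synonyms
            if kb.is_monosemous(syn) and usable_query_term(syn, stopwords)
        }
    )
    return synonyms, related_terms


def build_aec_queries(
    kb: KnowledgeBase, term: str, stopwords: frozenset[str] | None = None
) -> list[AecQuery]:
    """One query per candidate sense of an ambiguous term.

    Monosemous synonyms enter as single-phrase OR clauses; each
    monosemous related term enters as a conjunction with the ambiguous
    term itself (one sense per collocation).  A candidate with no usable
    relatives yields an empty, untrainable query.
    """
    from .preprocess import default_stopwords

    sw = stopwords if stopwords is not None else default_stopwords()
    candidates = kb.candidate_concepts(term)
    if len(candidates) < 2:
        raise ValueError(f"term {term!r} is not ambiguous in this knowledge base")
    queries = []
    for cui in sorted(candidates):
        synonyms, related = monosemous_relatives(kb, cui, sw)
        clauses = [QueryClause((syn,)) for syn in synonyms]
        clauses += [QueryClause((term, rel)) for rel in related]
        if not clauses:
            logger.warning("AEC: no usable relatives for %s (%s)", cui, term)
        queries.append(AecQuery(cui=cui, term=term, clauses=tuple(clauses)))
    return queries


# ---------------------------------------------------------------------
# Searchers
# ---------------------------------------------------------------------

class DocumentSearcher(Protocol):
    """Boolean search over document titles/abstracts."""

    def search(self, query: AecQuery, quoted: bool = True) -> list[str]:
        """Documents matching the query, in engine order."""
        ...


class OfflineSearcher:
    """Boolean matcher over an in-memory or on-disk document collection.

    Quoted phrases must occur as consecutive normalized tokens; the
    unquoted fallback only requires every phrase word to occur somewhere
    in the document.
    """

    def __init__(self, documents: Sequence[str]):
        self._docs = list(documents)
        self._tokens = [tokenize(d) for d in self._docs]
        self._vocab = [set(toks) for toks in self._tokens]

    @classmethod
    def from_directory(cls, directory: str | Path, pattern: str = "*.txt") -> "OfflineSearcher":
        paths = sorted(Path(directory).glob(pattern))
        return cls([p.read_text("utf-8") for p in paths])

    @staticmethod
    def _phrase_in(phrase_tokens: list[str], doc_tokens: list[str]) -> bool:
        n = len(phrase_tokens)
        if n == 0:
            return False
        return any(
            doc_tokens[i : i + n] == phrase_tokens
            for i in range(len(doc_tokens) - n + 1)
        )

    def _matches(self, query: AecQuery, doc_idx: int, quoted: bool) -> bool:
        for clause in query.clauses:
            ok = True
            for phrase in clause.phrases:
                words = tokenize(phrase)
                if quoted:
                    if not self._phrase_in(words, self._tokens[doc_idx]):
                        ok = False
                        break
                else:
                    if not set(words) <= self._vocab[doc_idx]:
                        ok = False
                        break
            if ok and clause.phrases:
                return True
        return False

    def search(self, query: AecQuery, quoted: bool = True) -> list[str]:
        if query.is_empty:
            return []
        return [
            self._docs[i]
            for i in range(len(self._docs))
            if self._matches(query, i, quoted)
        ]


class EUtilsSearcher:
    """Live PubMed retrieval through NCBI E-utilities.

    Provided for users who want real MEDLINE pseudo-corpora; it is never
    exercised by the test suite and requires network access.
    """

    ESEARCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"
    EFETCH = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

    def __init__(self, retmax: int = 100, email: str | None = None):
        self.retmax = retmax
        self.email = email

    def search(self, query: AecQuery, quoted: bool = True) -> list[str]:
        import json
        import urllib.parse
        import urllib.request

        expr = query.boolean_expression if quoted else query.fallback_expression
        params = {"db": "pubmed", "term": expr, "retmax": str(self.retmax),
                  "retmode": "json"}
        if self.email:
            params["email"] = self.email
        try:
            with urllib.request.urlopen(
                f"{self.ESEARCH}?{urllib.parse.urlencode(params)}", timeout=30
            ) as resp:
                ids = json.load(resp)["esearchresult"]["idlist"]
            if not ids:
                return []
            fetch = {"db": "pubmed", "id": ",".join(ids), "rettype": "abstract",
                     "retmode": "text"}
            with urllib.request.urlopen(
                f"{self.EFETCH}?{urllib.parse.urlencode(fetch)}", timeout=60
            ) as resp:
                text = resp.read().decode("utf-8", "replace")
        except Exception as exc:  # pragma: no cover - network dependent
            raise RetrievalError(str(exc)) from exc
        return [chunk.strip() for chunk in text.split("\n\n\n") if chunk.strip()]


def collect_training_corpus(
    queries: Iterable[AecQuery],
    searcher: DocumentSearcher,
    limit: int = 100,
) -> list[tuple[str, str]]:
    """Retrieve up to ``limit`` documents per candidate, labeled with the
    query's CUI.  The parenthesized fallback expression is tried when the
    quoted form returns nothing; a candidate with no documents after the
    fallback is left untrainable with a warning.
    """
    if limit < 1:
        raise ValueError("limit must be positive")
    corpus: list[tuple[str, str]] = []
    for query in queries:
        if query.is_empty:
            logger.warning("AEC: empty query for %s, candidate untrainable", query.cui)
            continue
        docs = searcher.search(query, quoted=True)
        if not docs:
            docs = searcher.search(query, quoted=False)
        if not docs:
            logger.warning("AEC: no documents for %s, candidate untrainable", query.cui)
            continue
        corpus.extend((doc, query.cui) for doc in docs[:limit])
    return corpus


# ---------------------------------------------------------------------
# Naive Bayes
# ---------------------------------------------------------------------

@dataclass
class NbModel:
    """Multinomial Naive Bayes parameters in log space.

    ``class_log_priors`` exponentiates to a distribution over trained
    CUIs; for each CUI the add-one-smoothed word likelihoods over the
    full vocabulary exponentiate to 1.
    """

    class_log_priors: dict[str, float]
    word_log_likelihoods: dict[tuple[str, str], float]
    vocabulary: set[str] = field(default_factory=set)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_log_priors)


def train_nb(
    corpus: Sequence[tuple[str, str]],
    stopwords: frozenset[str] | None = None,
) -> NbModel:
    """Fit add-one-smoothed multinomial Naive Bayes on preprocessed
    unigram bags of the labeled documents."""
    if not corpus:
        raise ValueError("empty training corpus")
    bags = [preprocess(text, stopwords) for text, _ in corpus]
    labels = [cui for _, cui in corpus]
    vocabulary = sorted({w for bag in bags for w in bag})
    if not vocabulary:
        raise ValueError("training corpus has no content words")
    word_idx = {w: j for j, w in enumerate(vocabulary)}
    X = np.zeros((len(bags), len(vocabulary)), dtype=np.float64)
    for i, bag in enumerate(bags):
        for w, count in bag.items():
            X[i, word_idx[w]] = count
    clf = MultinomialNB(alpha=1.0)
    clf.fit(X, labels)
    priors = {
        str(cls): float(lp) for cls, lp in zip(clf.classes_, clf.class_log_prior_)
    }
    likelihoods = {
        (str(cls), w): float(clf.feature_log_prob_[k, j])
        for k, cls in enumerate(clf.classes_)
        for w, j in word_idx.items()
    }
    return NbModel(
        class_log_priors=priors,
        word_log_likelihoods=likelihoods,
        vocabulary=set(vocabulary),
    )


def nb_log_posterior(
    model: NbModel, context: Counter, cui: str
) -> float:
    """Unnormalized log posterior of one class given a stemmed bag.

    Words outside the training vocabulary carry no evidence for any
    class and are ignored.
    """
    score = model.class_log_priors[cui]
    for w, count in context.items():
        if w in model.vocabulary:
            score += count * model.word_log_likelihoods[(cui, w)]
    return score


def aec_disambiguate(
    model: NbModel,
    inst: WsdInstance,
    stopwords: frozenset[str] | None = None,
) -> str:
    """Argmax Naive Bayes posterior over the instance's candidates.

    Candidates absent from the model (no training documents) are
    excluded with a warning; ties break toward the smallest CUI.
    """
    trained = [c for c in sorted(inst.candidates) if c in model.class_log_priors]
    untrained = sorted(inst.candidates - set(trained))
    if untrained:
        logger.warning("AEC: candidates without training data excluded: %s", untrained)
    if not trained:
        raise ValueError(f"no trained candidates for instance {inst.term!r}")
    context = preprocess(inst.context, stopwords)
    scored = [(cui, nb_log_posterior(model, context, cui)) for cui in trained]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[0][0]
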