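"""Recall-oriented n-gram overlap metrics for summary evaluation.

ROUGE-N counts the n-grams a peer summary shares with one or more
reference summaries and reports the clipped match count divided by the
total number of reference n-grams (a recall).  ROUGE-SU additionally
counts skip-bigrams — ordered word pairs at most ``skip`` positions
apart — pooled with unigrams, so a peer gets some credit for unigram
overlap even when no pair matches.  With several references, clipped
matches and totals are summed over the references (no jackknifing).

Tokenization is deliberately plain: lowercase, split on
non-alphanumerics, no stemming or stop-word removal unless requested.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

from ._porter import stem as _porter_stem
from .preprocess import default_stopwords, tokenize as _tokenize


class RougeError(Exception):
    pass


class UndefinedRougeError(RougeError):
    """All references were unusable (e.g. shorter than n)."""


def tokenize_summary(
    text: str,
    stem: bool = False,
    remove_stopwords: bool = False,
) -> list[str]:
    """Lowercased word tokens of a summary, optionally stemmed and
    stop-listed."""
    tokens = _tokenize(text)
    if remove_stopwords:
        sw = default_stopwords()
        tokens = [t for t in tokens if t not in sw]
    if stem:
        tokens = [_porter_stem(t) for t in tokens]
    return tokens


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _su_units(tokens: Sequence[str], skip: int) -> Counter:
    """Union multiset of unigrams and skip-bigrams with gap <= skip.

    A skip-bigram is an ordered pair (tokens[i], tokens[j]) with
    0 < j - i <= skip; adjacent words are at distance 1.
    """
    units: Counter = Counter()
    for i, tok in enumerate(tokens):
        units[("u", tok)] += 1
        for j in range(i + 1, min(i + skip + 1, len(tokens))):
            units[("sb", tok, tokens[j])] += 1
    return units


def _clipped_recall(
    peer_units: Counter, ref_unit_sets: list[Counter]
) -> float:
    matched = 0
    total = 0
    for ref_units in ref_unit_sets:
        total += sum(ref_units.values())
        overlap = peer_units & ref_units  # multiset min = clipped counts
        matched += sum(overlap.values())
    if total == 0:
        raise UndefinedRougeError("references contain no counting units")
    return matched / total


def rouge_n(
    peer: Sequence[str], refs: Sequence[Sequence[str]], n: int = 2
) -> float:
    """ROUGE-N recall of a tokenized peer against tokenized references.

    References shorter than ``n`` tokens contribute no n-grams and are
    skipped; if every reference is skipped the metric is undefined.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not refs:
        raise RougeError("at least one reference summary is required")
    peer_units = _ngrams(peer, n)
    ref_units = []
    for ref in refs:
        if len(ref) < n:
            import logging

            logging.getLogger(__name__).warning(
                "reference with %d tokens skipped for ROUGE-%d", len(ref), n
            )
            continue
        ref_units.append(_ngrams(ref, n))
    if not ref_units:
        raise UndefinedRougeError(f"no reference has >= {n} tokens")
    return _clipped_recall(peer_units, ref_units)


def rouge_su(
    peer: Sequence[str],
    refs: Sequence[Sequence[str]],
    skip: int = 4,
    include_unigrams: bool = True,
) -> float:
    """ROUGE-SU recall: skip-bigrams with gap <= ``skip`` pooled with
    unigrams (disable ``include_unigrams`` for pure skip-bigram S)."""
    if skip < 1:
        raise ValueError("skip must be positive")
    if not refs:
        raise RougeError("at least one reference summary is required")

    def units(tokens: Sequence[str]) -> Counter:
        u = _su_units(tokens, skip)
        if not include_unigrams:
            u = Counter({k: v for k, v in u.items() if k[0] == "sb"})
        return u

    ref_units = [units(ref) for ref in refs if ref]
    if not ref_units:
        raise UndefinedRougeError("all references are empty")
    return _clipped_recall(units(peer), ref_units)


def rouge_2(peer: Sequence[str], refs: Sequence[Sequence[str]]) -> float:
    return rouge_n(peer, refs, n=2)


def rouge_su4(peer: Sequence[str], refs: Sequence[Sequence[str]]) -> float:
    return rouge_su(peer, refs, skip=4)


def score_summary_text(
    peer_text: str,
    ref_texts: Sequence[str],
    stem: bool = False,
    remove_stopwords: bool = False,
) -> dict[str, float]:
    """Convenience wrapper: tokenize raw texts and report both metrics."""
    peer = tokenize_summary(peer_text, stem, remove_stopwords)
    refs = [tokenize_summary(t, stem, remove_stopwords) for t in ref_texts]
    return {"rouge2": rouge_2(peer, refs), "su4": rouge_su4(peer, refs)}
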