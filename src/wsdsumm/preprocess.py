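"""Text preprocessing shared by the disambiguators and the summarizer.

The pipeline is deliberately simple and deterministic: lowercase,
tokenize on non-alphanumeric boundaries, drop stop words, Porter-stem,
count.  The resulting bag of stemmed words (a ``ContextVector``) is the
unit every vector-space comparison in the package operates on.
"""

from __future__ import annotations

import re
from collections import Counter
from importlib import resources
from pathlib import Path

from ._porter import stem

ContextVector = Counter  # sparse map: stemmed word -> positive count

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


def default_stopwords() -> frozenset[str]:
    """The packaged English stop-word list."""
    text = resources.files("wsdsumm").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a custom stop list, one word per line."""
    return frozenset(
        w.strip().lower() for w in Path(path).read_text("utf-8").splitlines() if w.strip()
    )


_DEFAULT_STOPWORDS: frozenset[str] | None = None


def _stopwords(stopwords: frozenset[str] | None) -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if stopwords is not None:
        return stopwords
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = default_stopwords()
    return _DEFAULT_STOPWORDS


def tokenize(text: str) -> list[str]:
    """Lowercased alphanumeric tokens in order of appearance."""
    return _TOKEN_RE.findall(text.lower())


def preprocess_tokens(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Tokenize, remove stop words and Porter-stem, preserving order."""
    sw = _stopwords(stopwords)
    return [stem(tok) for tok in tokenize(text) if tok not in sw]


def preprocess(text: str, stopwords: frozenset[str] | None = None) -> ContextVector:
    """Turn free text into a sparse stemmed-word frequency vector.

    Stop words are removed before stemming, so a stem that collides with
    a stop word (e.g. "this" vs "thi") is preserved.
    """
    return Counter(preprocess_tokens(text, stopwords))


def normalize_term(term: str) -> str:
    """Canonical surface form used for dictionary lookups.

    Lowercases, strips punctuation at token boundaries and collapses
    internal whitespace, so that "Cold  Storage," and "cold storage"
    index identically.
    """
    return " ".join(tokenize(term))
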