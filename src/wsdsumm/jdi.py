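"""Journal Descriptor Indexing (JDI) disambiguation.

JDI resolves an ambiguous term through the semantic types of its
candidate concepts.  Journal descriptors (JDs) are broad MeSH headings
assigned to MEDLINE journals; each JD carries a word-probability vector
trained elsewhere, and each semantic type carries a pre-computed vector
of per-JD scores.  The context of the ambiguous word is indexed against
the JD word vectors (cosine), giving a per-JD score vector; each
candidate's semantic types are then ranked by the cosine between that
vector and the type's pre-computed JD indexing, and the candidate owning
the top-ranked type wins.

Training JD vectors from MEDLINE is outside this package's scope: a
``JdModel`` is consumed as an input (the fixtures module can synthesize
one).  By construction JDI must abstain whenever all candidates carry
the identical semantic-type set — type information then carries no
signal — and when the context provides no evidence at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .datasets import ABSTAIN, WsdInstance
from .kb import KnowledgeBase
from .mrd import cosine
from .preprocess import ContextVector, preprocess


class JdModelError(Exception):
    pass


@dataclass
class JdModel:
    """Pre-calculated journal-descriptor indexing.

    ``jd_vectors`` maps a JD id to a sparse word-probability vector;
    ``st_jd_index`` maps a semantic type to its per-JD score vector,
    keyed by JD id.  All values must lie in [0, 1].
    """

    jd_vectors: dict[str, dict[str, float]]
    st_jd_index: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for jd, vec in self.jd_vectors.items():
            for word, p in vec.items():
                if not 0.0 <= p <= 1.0:
                    raise JdModelError(f"jd {jd}: probability {p} for {word!r}")
        for st, vec in self.st_jd_index.items():
            for jd, score in vec.items():
                if not 0.0 <= score <= 1.0:
                    raise JdModelError(f"type {st}: score {score} for jd {jd}")

    @property
    def jd_ids(self) -> list[str]:
        return sorted(self.jd_vectors)

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"jd_vectors": self.jd_vectors, "st_jd_index": self.st_jd_index},
                indent=1,
                sort_keys=True,
            ),
            "utf-8",
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "JdModel":
        data = json.loads(Path(path).read_text("utf-8"))
        return cls(jd_vectors=data["jd_vectors"], st_jd_index=data["st_jd_index"])


def index_context(jd: JdModel, context: ContextVector) -> dict[str, float]:
    """Per-JD cosine scores of a stemmed context bag."""
    return {
        jd_id: cosine(context, jd.jd_vectors[jd_id]) for jd_id in jd.jd_ids
    }


def rank_semantic_types(
    jd: JdModel, context_jd: Mapping[str, float], types: set[str]
) -> list[tuple[str, float]]:
    """Semantic types scored by cosine against their JD indexing, best
    first; ties break alphabetically."""
    scored = []
    for st in sorted(types):
        if st not in jd.st_jd_index:
            raise JdModelError(f"semantic type {st!r} missing from st_jd_index")
        scored.append((st, cosine(context_jd, jd.st_jd_index[st])))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def jdi_disambiguate(
    inst: WsdInstance,
    kb: KnowledgeBase,
    jd: JdModel,
    stopwords: frozenset[str] | None = None,
) -> str:
    """Return the winning candidate CUI, or ABSTAIN.

    Abstains when every candidate shares the identical semantic-type
    set, or when the context carries no usable evidence (empty after
    preprocessing, or orthogonal to every JD word vector).
    """
    type_sets = {cui: kb.semantic_types(cui) for cui in inst.candidates}
    if len(set(type_sets.values())) == 1:
        return ABSTAIN
    context = preprocess(inst.context, stopwords)
    if not context:
        return ABSTAIN
    context_jd = index_context(jd, context)
    if all(score == 0.0 for score in context_jd.values()):
        return ABSTAIN
    all_types = set().union(*type_sets.values())
    ranking = rank_semantic_types(jd, context_jd, all_types)
    top_type = ranking[0][0]
    owners = sorted(cui for cui, types in type_sets.items() if top_type in types)
    return owners[0]
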