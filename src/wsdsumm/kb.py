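"""Concept knowledge base: the UMLS-like resource every method consults.

The data model mirrors the structure of the UMLS Metathesaurus and
Semantic Network at the granularity the algorithms need: concepts with a
unique identifier (CUI), synonyms, semantic types and optional
definitions; typed relations between concepts (``is_a`` hypernymy and
``other_related``); and symmetric associations between semantic types.

Two on-disk dialects are supported: a documented TSV layout (the
authoritative format for this package) and a best-effort reader for the
pipe-delimited UMLS RRF files (MRCONSO/MRSTY/MRDEF/MRREL) for users with
a UMLS license.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .preprocess import normalize_term

RelationKind = Literal["is_a", "other_related"]


class KbError(Exception):
    """Base class for knowledge-base errors."""


class KbParseError(KbError):
    """A malformed line in a knowledge-base file."""


class KbIntegrityError(KbError):
    """Structurally invalid knowledge base (dangling endpoints, cycles...)."""


class KbLookupError(KbError, KeyError):
    """A CUI that does not exist in the knowledge base."""


@dataclass
class Concept:
    """One Metathesaurus-style concept (a single sense of its terms)."""

    cui: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    semantic_types: set[str] = field(default_factory=set)
    definitions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.synonyms = set(self.synonyms) | {self.preferred_name}
        if not self.semantic_types:
            raise KbIntegrityError(f"concept {self.cui} has no semantic types")


@dataclass(frozen=True)
class Relation:
    source: str
    kind: RelationKind
    target: str

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise KbIntegrityError(f"self-loop relation on {self.source}")
        if self.kind not in ("is_a", "other_related"):
            raise KbParseError(f"unknown relation kind {self.kind!r}")


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class KnowledgeBase:
    """In-memory concept knowledge base with a term->candidates index.

    ``is_a`` relations are directed parent->child and must form a DAG.
    Term lookups are case-insensitive after normalization (lowercase,
    punctuation stripped at token boundaries, whitespace collapsed).
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        relations: Iterable[Relation] = (),
        st_associations: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.cui in self.concepts:
                raise KbIntegrityError(f"duplicate cui {c.cui}")
            self.concepts[c.cui] = c
        self.relations: list[Relation] = list(relations)
        self.st_associations: set[tuple[str, str]] = {
            _canonical_pair(a, b) for a, b in st_associations
        }
        self._validate_relations()
        self._build_indexes()

    # -- construction -------------------------------------------------

    def _validate_relations(self) -> None:
        for rel in self.relations:
            for endpoint in (rel.source, rel.target):
                if endpoint not in self.concepts:
                    raise KbIntegrityError(
                        f"relation {rel.source}-[{rel.kind}]->{rel.target} "
                        f"references unknown cui {endpoint}"
                    )
        # is_a acyclicity via iterative DFS
        children: dict[str, list[str]] = {}
        for rel in self.relations:
            if rel.kind == "is_a":
                children.setdefault(rel.source, []).append(rel.target)
        state: dict[str, int] = {}  # 1 = on stack, 2 = done
        for start in children:
            if state.get(start):
                continue
            stack = [(start, iter(children.get(start, ())))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if state.get(nxt) == 1:
                        raise KbIntegrityError(f"is_a cycle through {nxt}")
                    if not state.get(nxt):
                        state[nxt] = 1
                        stack.append((nxt, iter(children.get(nxt, ()))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 2
                    stack.pop()

    def _build_indexes(self) -> None:
        self.term_index: dict[str, set[str]] = {}
        for c in self.concepts.values():
            for syn in c.synonyms:
                self.term_index.setdefault(normalize_term(syn), set()).add(c.cui)
        self._parents: dict[str, set[str]] = {}
        self._children: dict[str, set[str]] = {}
        self._other: dict[str, set[str]] = {}
        for rel in self.relations:
            if rel.kind == "is_a":
                self._parents.setdefault(rel.target, set()).add(rel.source)
                self._children.setdefault(rel.source, set()).add(rel.target)
            else:
                self._other.setdefault(rel.source, set()).add(rel.target)
                self._other.setdefault(rel.target, set()).add(rel.source)

    # -- lookups ------------------------------------------------------

    def _require(self, cui: str) -> Concept:
        try:
            return self.concepts[cui]
        except KeyError:
            raise KbLookupError(cui) from None

    def candidate_concepts(self, term: str) -> set[str]:
        """All CUIs whose synonym set contains the normalized term."""
        return set(self.term_index.get(normalize_term(term), ()))

    def is_monosemous(self, term: str) -> bool:
        """True iff the term maps to exactly one concept."""
        return len(self.candidate_concepts(term)) == 1

    def parents(self, cui: str) -> set[str]:
        self._require(cui)
        return set(self._parents.get(cui, ()))

    def children(self, cui: str) -> set[str]:
        self._require(cui)
        return set(self._children.get(cui, ()))

    def other_related(self, cui: str) -> set[str]:
        self._require(cui)
        return set(self._other.get(cui, ()))

    def semantic_types(self, cui: str) -> frozenset[str]:
        return frozenset(self._require(cui).semantic_types)

    def types_associated(self, type_a: str, type_b: str) -> bool:
        return _canonical_pair(type_a, type_b) in self.st_associations

    def hypernym_chain(self, cui: str) -> list[str]:
        """Path from the hierarchy root down to ``cui`` along is_a edges.

        The root (depth 1) comes first.  When a concept has several
        parents the chain follows the lexicographically smallest parent
        CUI, giving each concept a single deterministic hierarchy.
        """
        self._require(cui)
        chain = [cui]
        seen = {cui}
        node = cui
        while True:
            parents = self._parents.get(node)
            if not parents:
                break
            node = min(parents)
            if node in seen:  # defensive; validation rejects cycles
                raise KbIntegrityError(f"is_a cycle through {node}")
            seen.add(node)
            chain.append(node)
        chain.reverse()
        return chain

    def depth(self, cui: str) -> int:
        """Hierarchy depth of a concept; the root has depth 1."""
        return len(self.hypernym_chain(cui))

    def profile_sources(self, cui: str) -> list[str]:
        """Raw strings from which a concept's sense profile is built.

        Concatenates the concept's definitions and synonyms with the
        synonyms and definitions of directly related concepts — is_a
        parents and children plus ``other_related`` neighbours.  Siblings
        (concepts sharing a parent without a direct relation) contribute
        nothing, so two co-hyponym senses keep distinct profiles.
        """
        concept = self._require(cui)
        bag: list[str] = list(concept.definitions)
        bag.extend(sorted(concept.synonyms))
        related = self.parents(cui) | self.children(cui) | self.other_related(cui)
        for rel_cui in sorted(related):
            rel = self.concepts[rel_cui]
            bag.extend(sorted(rel.synonyms))
            bag.extend(rel.definitions)
        return bag

    # -- equality (used by round-trip checks) --------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            {c.cui: (c.preferred_name, frozenset(c.synonyms),
                     frozenset(c.semantic_types), tuple(sorted(c.definitions)))
             for c in self.concepts.values()}
            == {c.cui: (c.preferred_name, frozenset(c.synonyms),
                        frozenset(c.semantic_types), tuple(sorted(c.definitions)))
                for c in other.concepts.values()}
            and set(self.relations) == set(other.relations)
            and self.st_associations == other.st_associations
        )


# ---------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------

_CONCEPT_HEADER = ["cui", "preferred_name", "semantic_types", "definitions"]
_TERM_HEADER = ["term", "cui"]
_REL_HEADER = ["source_cui", "kind", "target_cui"]
_ST_HEADER = ["type_a", "type_b"]


def _read_tsv(path: Path, header: list[str]) -> list[list[str]]:
    if not path.exists():
        raise KbParseError(f"missing file: {path}")
    rows: list[list[str]] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            first = next(reader)
        except StopIteration:
            raise KbParseError(f"{path}: empty file, expected header {header}")
        if first != header:
            raise KbParseError(f"{path}:1: expected header {header}, got {first}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise KbParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    return rows


def load_kb_tsv(directory: str | Path) -> KnowledgeBase:
    """Load the TSV dialect: concepts.tsv, terms.tsv, relations.tsv,
    st_associations.tsv (the last two may be empty beyond the header)."""
    directory = Path(directory)
    concept_rows = _read_tsv(directory / "concepts.tsv", _CONCEPT_HEADER)
    term_rows = _read_tsv(directory / "terms.tsv", _TERM_HEADER)
    rel_rows = _read_tsv(directory / "relations.tsv", _REL_HEADER)
    st_rows = _read_tsv(directory / "st_associations.tsv", _ST_HEADER)

    synonyms: dict[str, set[str]] = {}
    for term, cui in term_rows:
        synonyms.setdefault(cui, set()).add(term)

    concepts = []
    for cui, name, sts, defs in concept_rows:
        concepts.append(
            Concept(
                cui=cui,
                preferred_name=name,
                synonyms=synonyms.get(cui, set()),
                semantic_types={t for t in sts.split("|") if t},
                definitions=[d for d in defs.split("|") if d],
            )
        )
    known = {c.cui for c in concepts}
    for term, cui in term_rows:
        if cui not in known:
            raise KbIntegrityError(f"terms.tsv references unknown cui {cui}")
    relations = [Relation(src, kind, tgt) for src, kind, tgt in rel_rows]  # type: ignore[arg-type]
    return KnowledgeBase(concepts, relations, [(a, b) for a, b in st_rows])


def save_kb_tsv(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write a knowledge base back to the TSV dialect (sorted, stable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def write(name: str, header: list[str], rows: Iterable[Iterable[str]]) -> None:
        with (directory / name).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    write(
        "concepts.tsv",
        _CONCEPT_HEADER,
        (
            [c.cui, c.preferred_name, "|".join(sorted(c.semantic_types)),
             "|".join(c.definitions)]
            for c in sorted(kb.concepts.values(), key=lambda c: c.cui)
        ),
    )
    write(
        "terms.tsv",
        _TERM_HEADER,
        sorted(
            (syn, c.cui)
            for c in kb.concepts.values()
            for syn in c.synonyms
        ),
    )
    write(
        "relations.tsv",
        _REL_HEADER,
        sorted((r.source, r.kind, r.target) for r in set(kb.relations)),
    )
    write("st_associations.tsv", _ST_HEADER, sorted(kb.st_associations))


# ---------------------------------------------------------------------
# UMLS RRF (best-effort convenience reader)
# ---------------------------------------------------------------------

def load_kb_rrf(directory: str | Path, language: str = "ENG") -> KnowledgeBase:
    """Read MRCONSO/MRSTY/MRDEF/MRREL pipe-delimited RRF files.

    Only the columns the data model needs are consumed: MRCONSO supplies
    terms (preferred name = first occurrence), MRSTY semantic types,
    MRDEF definitions, MRREL PAR/CHD edges as ``is_a`` and RO edges as
    ``other_related``.  Intended as a convenience for licensed UMLS
    users; the TSV dialect is the authoritative format.
    """
    directory = Path(directory)

    def rows(name: str):
        path = directory / name
        if not path.exists():
            return
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                yield line.rstrip("\n").split("|")

    names: dict[str, str] = {}
    syns: dict[str, set[str]] = {}
    for r in rows("MRCONSO.RRF"):
        cui, lat, term = r[0], r[1], r[14]
        if lat != language or not term:
            continue
        names.setdefault(cui, term)
        syns.setdefault(cui, set()).add(term)
    types: dict[str, set[str]] = {}
    for r in rows("MRSTY.RRF"):
        types.setdefault(r[0], set()).add(r[3])
    defs: dict[str, list[str]] = {}
    for r in rows("MRDEF.RRF"):
        defs.setdefault(r[0], []).append(r[5])
    concepts = [
        Concept(cui, names[cui], syns[cui], types.get(cui, {"Unknown"}), defs.get(cui, []))
        for cui in names
    ]
    relations: list[Relation] = []
    seen: set[tuple[str, str, str]] = set()
    for r in rows("MRREL.RRF"):
        cui1, rel, cui2 = r[0], r[3], r[4]
        if cui1 not in names or cui2 not in names or cui1 == cui2:
            continue
        if rel == "PAR":  # cui2 is parent of cui1
            key = (cui2, "is_a", cui1)
        elif rel == "CHD":
            key = (cui1, "is_a", cui2)
        elif rel == "RO":
            key = (cui1, "other_related", cui2)
        else:
            continue
        if key not in seen:
            seen.add(key)
            relations.append(Relation(*key))  # type: ignore[arg-type]
    return KnowledgeBase(concepts, relations)


def load_kb(path: str | Path, dialect: str = "tsv") -> KnowledgeBase:
    """Load a knowledge base from ``path`` in the given dialect."""
    if dialect == "tsv":
        return load_kb_tsv(path)
    if dialect == "rrf":
        return load_kb_rrf(path)
    raise ValueError(f"unknown dialect {dialect!r}")
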