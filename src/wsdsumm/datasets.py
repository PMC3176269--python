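"""WSD instance sets and the accuracy metric.

A dataset emulates the shape of the NLM WSD and MSH WSD collections:
each instance is one occurrence of an ambiguous surface term together
with its context text, the set of candidate concept identifiers and,
for evaluation, the gold concept.  Accuracy is simply the fraction of
instances predicted correctly; the *JDI subset* variant first removes
instances whose candidates all share the same semantic-type set, since
a type-based method cannot separate those senses by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .kb import KnowledgeBase

#: Sentinel returned by disambiguators that decline to predict.
ABSTAIN = "ABSTAIN"


class DatasetError(Exception):
    pass


class UndefinedMetricError(DatasetError):
    """Raised when accuracy is requested over zero instances."""


@dataclass(frozen=True)
class WsdInstance:
    term: str
    context: str
    candidates: frozenset[str]
    gold: str | None = None

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise DatasetError(
                f"instance for {self.term!r} needs >=2 candidates, "
                f"got {sorted(self.candidates)}"
            )
        if self.gold is not None and self.gold not in self.candidates:
            raise DatasetError(
                f"gold {self.gold} not among candidates for {self.term!r}"
            )


@dataclass
class WsdDataset:
    instances: list[WsdInstance] = field(default_factory=list)
    name: str = "wsd"

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def terms(self) -> list[str]:
        return sorted({inst.term for inst in self.instances})


def shares_semantic_types(kb: KnowledgeBase, inst: WsdInstance) -> bool:
    """True when every candidate carries the identical semantic-type set."""
    type_sets = {kb.semantic_types(cui) for cui in inst.candidates}
    return len(type_sets) == 1


def wsd_accuracy(
    predictions: Mapping[WsdInstance, str],
    dataset: WsdDataset,
    subset_mode: str = "all",
    kb: KnowledgeBase | None = None,
) -> float:
    """Fraction of instances predicted correctly.

    ``subset_mode="jdi_subset"`` restricts to instances whose candidates
    do not all share one semantic-type set (requires ``kb``).  An
    ABSTAIN prediction counts as incorrect: the denominator is always
    every instance retained.
    """
    if subset_mode not in ("all", "jdi_subset"):
        raise ValueError(f"unknown subset_mode {subset_mode!r}")
    instances = list(dataset.instances)
    if subset_mode == "jdi_subset":
        if kb is None:
            raise ValueError("jdi_subset filtering requires the knowledge base")
        instances = [i for i in instances if not shares_semantic_types(kb, i)]
    if not instances:
        raise UndefinedMetricError("no instances left to score")
    missing = [i for i in instances if i not in predictions]
    if missing:
        raise DatasetError(f"predictions missing for {len(missing)} instances")
    correct = sum(1 for i in instances if predictions[i] == i.gold)
    return correct / len(instances)


# ---------------------------------------------------------------------
# TSV I/O: term, context, pipe-joined candidates, gold (empty = none)
# ---------------------------------------------------------------------

_HEADER = ["term", "context", "candidates", "gold"]


def load_dataset_tsv(
    path: str | Path,
    name: str | None = None,
    keep_unlabeled: bool = False,
) -> WsdDataset:
    """Read a dataset; instances without a gold sense ("none of the
    above" annotations) are dropped unless ``keep_unlabeled``."""
    path = Path(path)
    instances: list[WsdInstance] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HEADER:
            raise DatasetError(f"{path}: expected header {_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise DatasetError(f"{path}:{lineno}: expected 4 fields")
            term, context, cands, gold = row
            if not gold and not keep_unlabeled:
                continue
            instances.append(
                WsdInstance(
                    term=term,
                    context=context,
                    candidates=frozenset(c for c in cands.split("|") if c),
                    gold=gold or None,
                )
            )
    return WsdDataset(instances=instances, name=name or path.stem)


def save_dataset_tsv(dataset: WsdDataset, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for inst in dataset.instances:
            writer.writerow(
                [inst.term, inst.context, "|".join(sorted(inst.candidates)),
                 inst.gold or ""]
            )


def iter_by_term(dataset: WsdDataset) -> Iterable[tuple[str, list[WsdInstance]]]:
    by_term: dict[str, list[WsdInstance]] = {}
    for inst in dataset.instances:
        by_term.setdefault(inst.term, []).append(inst)
    for term in sorted(by_term):
        yield term, by_term[term]
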