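"""End-to-end evaluation pipelines: WSD accuracy tables and
summarization ROUGE tables, plus the pairwise agreement analysis.

``run_wsd_eval`` mirrors the usual accuracy layout (method by
set/subset, with a per-term breakdown); ``run_summarization_eval``
produces per-document and mean ROUGE-2 / ROUGE-SU4 per WSD method,
per-document win tallies, and — for each pair of methods — the
proportion of common mappings against the ROUGE-2 difference.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .aec import DocumentSearcher, aec_disambiguate, build_aec_queries, \
    collect_training_corpus, train_nb
from .datasets import ABSTAIN, UndefinedMetricError, WsdDataset, iter_by_term, \
    shares_semantic_types, wsd_accuracy
from .jdi import JdModel, jdi_disambiguate
from .kb import KnowledgeBase
from .mrd import build_all_profiles, mrd_disambiguate
from .rouge import score_summary_text
from .summarizer import WSD_METHODS, ConfigurationError, common_mapping_agreement, \
    make_resolver, summarize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible run configuration (YAML-loadable, CLI-overridable)."""

    kb_path: str = ""
    method: str = "mrd"
    compression: float = 0.30
    hub_fraction: float = 0.1
    seed: int = 0
    aec_limit: int = 100
    generic_types: list[str] = field(default_factory=list)
    stoplist_path: str | None = None
    jd_model_path: str | None = None
    search_corpus_path: str | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0.0 < self.compression <= 1.0:
            raise ConfigurationError("compression must lie in (0, 1]")
        if not 0.0 < self.hub_fraction <= 1.0:
            raise ConfigurationError("hub_fraction must lie in (0, 1]")
        if self.method not in WSD_METHODS:
            raise ConfigurationError(f"method must be one of {WSD_METHODS}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def log_provenance(self) -> None:
        logger.info(
            "run config: seed=%d hash=%s wsdsumm=%s", self.seed,
            self.config_hash(), __version__,
        )


# ---------------------------------------------------------------------
# WSD evaluation
# ---------------------------------------------------------------------

def predict_dataset(
    kb: KnowledgeBase,
    dataset: WsdDataset,
    method: str,
    jd_model: JdModel | None = None,
    searcher: DocumentSearcher | None = None,
    stopwords: frozenset[str] | None = None,
    aec_limit: int = 100,
) -> dict:
    """Predictions of one method for every instance of a dataset."""
    if method not in WSD_METHODS:
        raise ConfigurationError(f"unknown method {method!r}")
    predictions = {}
    if method == "first_mapping":
        for inst in dataset:
            predictions[inst] = min(inst.candidates)
    elif method == "mrd":
        profiles = build_all_profiles(kb, stopwords)
        for inst in dataset:
            predictions[inst] = mrd_disambiguate(
                set(inst.candidates), inst.context, profiles, stopwords
            )
    elif method == "jdi":
        if jd_model is None:
            raise ConfigurationError("jdi evaluation requires a JdModel")
        for inst in dataset:
            predictions[inst] = jdi_disambiguate(inst, kb, jd_model, stopwords)
    else:  # aec
        if searcher is None:
            raise ConfigurationError("aec evaluation requires a document searcher")
        for term, instances in iter_by_term(dataset):
            queries = build_aec_queries(kb, term, stopwords)
            corpus = collect_training_corpus(queries, searcher, limit=aec_limit)
            if not corpus:
                for inst in instances:
                    predictions[inst] = ABSTAIN
                continue
            model = train_nb(corpus, stopwords)
            for inst in instances:
                try:
                    predictions[inst] = aec_disambiguate(model, inst, stopwords)
                except ValueError:
                    predictions[inst] = ABSTAIN
    return predictions


def run_wsd_eval(
    kb: KnowledgeBase,
    dataset: WsdDataset,
    methods: Sequence[str] = ("mrd", "aec", "jdi", "first_mapping"),
    jd_model: JdModel | None = None,
    searcher: DocumentSearcher | None = None,
    stopwords: frozenset[str] | None = None,
    aec_limit: int = 100,
) -> dict[str, pd.DataFrame]:
    """Accuracy of each method over the whole set and the JDI subset.

    Returns ``{"summary": method x {set, jdi_subset}, "by_term":
    per-term accuracies}``.
    """
    summary_rows = []
    term_rows = []
    for method in methods:
        preds = predict_dataset(
            kb, dataset, method, jd_model, searcher, stopwords, aec_limit
        )
        row = {"method": method,
               "set": wsd_accuracy(preds, dataset, "all")}
        try:
            row["jdi_subset"] = wsd_accuracy(preds, dataset, "jdi_subset", kb)
        except UndefinedMetricError:
            row["jdi_subset"] = float("nan")
        summary_rows.append(row)
        for term, instances in iter_by_term(dataset):
            correct = sum(1 for i in instances if preds[i] == i.gold)
            term_rows.append(
                {
                    "method": method,
                    "term": term,
                    "n": len(instances),
                    "accuracy": correct / len(instances),
                    "jdi_eligible": not shares_semantic_types(kb, instances[0]),
                }
            )
    return {
        "summary": pd.DataFrame(summary_rows),
        "by_term": pd.DataFrame(term_rows),
    }


# ---------------------------------------------------------------------
# Summarization evaluation
# ---------------------------------------------------------------------

def run_summarization_eval(
    kb: KnowledgeBase,
    corpus,
    methods: Sequence[str] = ("mrd", "aec", "jdi", "first_mapping"),
    compression: float = 0.30,
    hub_fraction: float = 0.1,
    jd_model: JdModel | None = None,
    searcher: DocumentSearcher | None = None,
    stopwords: frozenset[str] | None = None,
    aec_limit: int = 100,
) -> dict[str, pd.DataFrame]:
    """ROUGE-2 / ROUGE-SU4 per document and per WSD method.

    ``corpus`` is a sequence of objects with ``doc_id``, ``sentences``
    and ``reference`` (e.g. :class:`~wsdsumm.fixtures.SummDocument`).
    Returns per-document scores, method means, per-document win tallies
    (highest ROUGE-2 per document, and pairwise better-than counts) and
    the common-mapping agreement vs ROUGE-2 difference pairs.
    """
    if not corpus:
        raise ValueError("empty summarization corpus")
    for doc in corpus:
        if not getattr(doc, "reference", ""):
            raise ValueError(f"document {doc.doc_id} has no reference summary")

    resolvers = {
        m: make_resolver(
            kb, m, jd_model=jd_model, searcher=searcher, stopwords=stopwords,
            aec_limit=aec_limit,
        )
        for m in methods
    }
    score_rows = []
    mappings: dict[tuple[str, str], list] = {}
    for doc in corpus:
        for method in methods:
            result = summarize(
                doc.sentences, kb, resolver=resolvers[method],
                compression=compression, hub_fraction=hub_fraction,
            )
            scores = score_summary_text(result.summary_text, [doc.reference])
            score_rows.append(
                {
                    "doc_id": doc.doc_id,
                    "method": method,
                    "rouge2": scores["rouge2"],
                    "su4": scores["su4"],
                    "n_selected": len(result.selected),
                }
            )
            mappings[(doc.doc_id, method)] = result.mappings
    scores_df = pd.DataFrame(score_rows)
    means = (
        scores_df.groupby("method")[["rouge2", "su4"]].mean().reset_index()
    )

    pivot = scores_df.pivot(index="doc_id", columns="method", values="rouge2")
    win_rows = []
    for method in methods:
        best = int((pivot[method] >= pivot.max(axis=1)).sum())
        row = {"method": method, "best_rouge2_docs": best}
        for other in methods:
            if other != method:
                row[f"beats_{other}"] = int((pivot[method] > pivot[other]).sum())
        win_rows.append(row)

    agreement_rows = []
    ordered = list(methods)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            for doc in corpus:
                try:
                    agreement = common_mapping_agreement(
                        mappings[(doc.doc_id, a)], mappings[(doc.doc_id, b)]
                    )
                except UndefinedMetricError:
                    continue
                r_a = scores_df.query(
                    "doc_id == @doc.doc_id and method == @a"
                )["rouge2"].iloc[0]
                r_b = scores_df.query(
                    "doc_id == @doc.doc_id and method == @b"
                )["rouge2"].iloc[0]
                agreement_rows.append(
                    {
                        "doc_id": doc.doc_id,
                        "method_a": a,
                        "method_b": b,
                        "common_mapping_agreement": agreement,
                        "rouge2_diff": abs(r_a - r_b),
                    }
                )
    return {
        "scores": scores_df,
        "means": means,
        "wins": pd.DataFrame(win_rows),
        "agreement": pd.DataFrame(agreement_rows),
    }
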