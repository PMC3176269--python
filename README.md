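# wsdsumm

Knowledge-based word sense disambiguation and graph-based extractive
summarization for biomedical text, over a UMLS-like concept knowledge
base, with ROUGE evaluation and fully synthetic test fixtures.

## The problem

When biomedical text is mapped onto a concept thesaurus such as the UMLS
Metathesaurus, many surface phrases are ambiguous: "cold" may denote the
common cold (a disease), a cold sensation, or cold temperature, each a
distinct concept (CUI) with its own semantic type.  A concept-based
summarizer that picks the wrong mapping mistakes what a sentence is
about, so word sense disambiguation (WSD) quality propagates into
summary quality.  This package implements, end to end:

* **Three knowledge-based WSD methods.**
  * **MRD** (machine readable dictionary): each candidate concept *c* of
    an ambiguous word *w* gets a profile vector built from its
    definitions, synonyms and directly related concepts (siblings
    excluded), weighted tf × icf; the context vector *cx* picks
    `MRD(w) = argmax_{c ∈ C_w} (c · cx) / (|c||cx|)`.
  * **AEC** (automatic extracted corpus): boolean queries built from the
    monosemous relatives of each candidate sense retrieve pseudo-labeled
    training documents (offline searcher included; optional E-utilities
    client), which train a multinomial Naive Bayes sense classifier.
  * **JDI** (journal descriptor indexing): the context is indexed
    against journal-descriptor word vectors, candidate senses are ranked
    through the JD indexing of their semantic types, and the method
    abstains when every candidate carries the same semantic-type set.
* **A four-step graph summarizer**: dictionary concept mapping with
  pluggable WSD (or the no-WSD *first mapping* baseline), document-graph
  construction over hypernym chains (is_a edge weight
  `depth(parent)/depth(child)`, other relations weight 1), hub-vertex-set
  (HVS) clustering by salience, and non-democratic sentence voting
  `Score(S_j) = Σ_i similarity(C_i, S_j) / |C_i|`, selecting sentences
  until the summary reaches 30% of the body.
* **ROUGE-2 and ROUGE-SU4** recall metrics against reference summaries.
* **Synthetic fixtures**: a deterministic generator for knowledge bases,
  WSD datasets with controllable sense separability, pseudo-MEDLINE
  search corpora, JD models, and documents with planted topics — so the
  whole pipeline runs without the licensed UMLS, MetaMap or any network.

## Worked example

```python
from wsdsumm import (FixtureSpec, OfflineSearcher, generate_corpus,
                     generate_jd_model, generate_kb, generate_search_corpus,
                     generate_wsd_dataset, summarize, wsd_accuracy)
from wsdsumm.evaluate import predict_dataset
from wsdsumm.rouge import score_summary_text

spec = FixtureSpec(seed=42, n_documents=20)
kb = generate_kb(spec)
dataset = generate_wsd_dataset(kb, spec)
searcher = OfflineSearcher(generate_search_corpus(kb, spec))
jd = generate_jd_model(kb, spec)

for method in ("mrd", "aec", "jdi", "first_mapping"):
    preds = predict_dataset(kb, dataset, method, jd_model=jd, searcher=searcher)
    print(f"{method:>14}: accuracy = {wsd_accuracy(preds, dataset):.3f}")

doc = generate_corpus(kb, spec)[0]
for method in ("mrd", "first_mapping"):
    result = summarize(doc.sentences, kb, wsd=method, compression=0.30)
    scores = score_summary_text(result.summary_text, [doc.reference])
    print(f"{method:>14}: selected {result.selected}  "
          f"ROUGE-2 = {scores['rouge2']:.3f}  ROUGE-SU4 = {scores['su4']:.3f}")
```

prints

```
           mrd: accuracy = 1.000
           aec: accuracy = 1.000
           jdi: accuracy = 1.000
 first_mapping: accuracy = 0.540
           mrd: selected [0, 8, 9]  ROUGE-2 = 1.000  ROUGE-SU4 = 1.000
 first_mapping: selected [0, 1, 2]  ROUGE-2 = 0.310  ROUGE-SU4 = 0.286
```

At full sense separability every real disambiguator is perfect while the
first-mapping baseline sits near chance (the generator orders candidate
CUIs adversarially), and the summarizer recovers exactly the planted
topic sentences under MRD (ROUGE-2 = 1.0) but not under the baseline —
the qualitative pattern that motivates putting WSD in front of a
concept-graph summarizer.

## Command line

```bash
wsdsumm gen-fixtures --seed 7 --out fx
wsdsumm wsd-eval  --kb fx/kb --dataset fx/wsd_dataset.tsv \
                  --jd-model fx/jd_model.json --search-corpus fx/search_corpus --out reports
wsdsumm summarize --kb fx/kb --doc fx/corpus/doc000.txt --wsd mrd \
                  --one-per-line --compression 0.30 --report report.json
wsdsumm rouge     --peer summary.txt --ref fx/corpus/doc000.ref.txt
wsdsumm agreement --kb fx/kb --doc fx/corpus/doc000.txt --methods mrd,first_mapping --one-per-line
wsdsumm summ-eval --kb fx/kb --fixtures fx --out reports
```

Knowledge bases load from a documented TSV dialect (`concepts.tsv`,
`terms.tsv`, `relations.tsv`, `st_associations.tsv`); a best-effort
reader for UMLS RRF files (MRCONSO/MRSTY/MRDEF/MRREL) is included for
licensed users.  See `docs/methods.md` for the model details, parameter
defaults and known limitations.

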