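# Methods

This note documents the models implemented in `wsdsumm`, the choices
made where the underlying methods leave details open, what the synthetic
generators emulate, and the limits of what the test results show.

## Knowledge base

The knowledge base mirrors the parts of the UMLS that the algorithms
consume: concepts with a unique identifier (CUI), synonyms, one or more
semantic types and optional definitions; directed `is_a` relations
(parent → child) forming a DAG; undirected `other_related` relations;
and symmetric associations between semantic types (the Semantic-Network
role of *associated with*).  Term lookup normalizes surface forms by
lowercasing, stripping punctuation at token boundaries and collapsing
whitespace — a deterministic stand-in for MetaMap-style lexical
matching, which is out of scope.

Two open details are fixed as follows:

* **Multiple `is_a` parents.** A concept's hypernym chain follows the
  lexicographically smallest parent CUI, giving every concept a single
  deterministic hierarchy (root depth 1).
* **"Related concepts excluding siblings"** in profile construction is
  read as *directly* related concepts only: `is_a` parents and children
  plus `other_related` neighbours.  Siblings — co-children of a shared
  parent without a direct relation — are excluded, which keeps the
  profiles of co-hyponym senses distinct.

## Preprocessing

All vector-space text handling shares one pipeline: lowercase, tokenize
on non-alphanumeric boundaries, remove stop words, then Porter-stem.
The stemmer is an in-package implementation of the classic five-step
algorithm, verified against the canonical example list.  The stop list
is a packaged standard English list (~170 entries) and can be replaced
by a file path everywhere it is used.

## MRD

Each candidate concept's profile weight for stemmed word *w* is
`tf(w) × icf(w)` with

```
icf(w) = log((1 + N) / (1 + n_w)) + 1
```

where `N` is the number of concepts in the knowledge base and `n_w` the
number of concepts whose profile sources contain *w*.  The method names
an "inverted concept frequency" without a formula; this smoothed form is
strictly positive, equals 1 for a word present in every concept and
grows logarithmically with rarity — the standard smoothed-idf shape with
concepts as documents.  The context is a raw-frequency vector over the
same preprocessing; the candidate with the highest cosine wins.  All
ties — including the all-zero-similarity case — break toward the
lexicographically smallest CUI, making the ranker deterministic.

## AEC

For each candidate sense, monosemous synonyms become quoted single-phrase
clauses and each monosemous term of a directly related concept becomes a
conjunction with the ambiguous term (one sense per collocation); clauses
are OR-joined and tagged `[tiab]`.  Filters drop terms longer than 50
characters, shorter than 3, pure numbers and stop words.  If the quoted
query returns nothing, a fallback form replaces quotes with parentheses
(phrase words may then occur anywhere in the document).  Up to 100
documents per sense (configurable) are labeled with the query's CUI.

Retrieval goes through a small searcher interface.  The offline
implementation does exact boolean matching over a local document list
(quoted = consecutive normalized tokens) and is what the tests and
fixtures use; a thin E-utilities client with the same contract is
provided for live PubMed use and is never exercised in tests.

The classifier is multinomial Naive Bayes with add-one smoothing over
unigram bags (scikit-learn's `MultinomialNB` behind the module surface);
the feature set and smoothing are unspecified in the source method, so
the most common text-classification defaults are used.  Candidates that
obtained no training documents are excluded from the argmax with a
warning; prediction ties break toward the smallest CUI.

## JDI

Journal-descriptor vectors are consumed as an input (`JdModel`); training
them from MEDLINE is out of scope.  Disambiguation scores each JD by
cosine against the context bag, then scores each candidate semantic type
by cosine between that per-JD vector and the type's precomputed JD
indexing; the candidate owning the top-ranked type wins (type ties break
alphabetically, candidate ties by smallest CUI).  The method abstains
when (a) all candidates share an identical semantic-type set — type
information then carries no signal, which is the method's structural
blind spot — or (b) the context is empty or orthogonal to every JD
vector.  In the accuracy metric an abstention counts as incorrect, since
the denominator is all instances; the *JDI subset* variant removes the
shared-type instances before scoring.

## Summarizer

1. **Concept identification.** Greedy longest-match lookup of sentence
   token spans against the term index (no overlaps) yields candidate CUI
   sets per phrase, standing in for MetaMap's role of emitting candidate
   mappings; precomputed mapping files can be injected instead.
   Singleton sets are accepted; larger sets are resolved by the chosen
   WSD method with the sentence as context (JDI falls back to the first
   mapping when it abstains).  Concepts whose semantic types all belong
   to the generic list (Quantitative/Qualitative/Temporal/Functional
   concept, Idea or concept, Intellectual product, Mental process,
   Spatial concept, Language) are discarded.
2. **Document representation.** Sentence concepts are extended with
   their full hypernym chains; the two most abstract levels are removed
   (vertices keep their untrimmed depth, which keeps the is_a weight
   `depth(parent)/depth(child)` in (0, 1] and never divides by zero).
   Sentence graphs merge into a document graph enriched with
   `other_related` edges between any related vertex pair and
   `associated_with` edges between *leaf* vertices (vertices that parent
   nothing in the graph) whose types are associated; both weigh 1.
3. **Topic recognition.** Salience = summed incident edge weight.  The
   top `max(1, ⌈hub_fraction·|V|⌉)` vertices (default `hub_fraction`
   0.1; the hub count is unspecified in the source method) are hubs;
   connected components of the hub-induced subgraph are the HVS
   centroids.  Non-hub vertices are assigned in descending salience
   order to the cluster with the largest summed edge weight to current
   members, updating membership as assignment proceeds; vertices with no
   edge into any cluster stay unassigned.  All orderings and tie-breaks
   (smaller CUI, earlier cluster) are fixed for determinism.
4. **Sentence selection.** A sentence vertex votes 1 for a cluster
   containing it in its HVS, 0.5 as a plain member, 0 otherwise;
   sentence score is the size-adjusted vote sum over clusters.
   Sentences are taken by descending score (ties to the earlier
   sentence) until the summary first reaches `compression` (default
   0.30) of the body size.  "Size" is word count by default — robust to
   heterogeneous sentence lengths — with a sentence-count mode
   available.  Duplicate concepts within a sentence do not multiply
   votes (vertex sets); clustering is computed once per document.

The *common mapping agreement* between two WSD configurations is the
fraction of ambiguous phrase occurrences (more than one candidate) on
which both chose the same concept; both runs must cover identical
occurrences.

## ROUGE

ROUGE-N is clipped n-gram recall: matched counts (capped at the
reference count) summed over references, divided by total reference
n-grams; multiple references use the summation form, no jackknifing.
ROUGE-SU pools unigrams with skip-bigrams — ordered pairs `(t_i, t_j)`
with `0 < j − i ≤ skip`, adjacent words at distance 1 — with skip
distance 4 by default.  The SU definition includes unigrams, as is
standard for "SU"; a flag yields pure skip-bigram S.  Tokenization is
lowercase, split on non-alphanumerics, with no stemming or stop-word
removal unless requested, since the metrics' preprocessing is otherwise
unspecified.

## Synthetic data

The generators are pure functions of a `FixtureSpec` (all randomness
from its seed; artifacts are byte-identical on re-run).  They emulate
the *structure* of the real resources, not their statistics:

* **Knowledge base**: an `is_a` forest of the requested depth
  (default 4), integer-coded private vocabularies ("w0017") of
  `vocabulary_size` words per concept, so separability is exactly
  controllable.  Each ambiguous term attaches to `senses_per_term`
  deepest-level concepts.  The smallest-CUI sense of every term is a
  decoy carrying only a generic semantic type ("Quantitative concept"),
  so the first-mapping baseline is adversarially wrong and the decoy is
  filtered inside the summarizer; other senses get distinct dedicated
  types (or one shared type with `shared_semantic_types=True`, the
  JDI-abstention regime).  Each non-decoy sense has a sibling partner
  whose type is associated with the sense's type, producing
  `associated_with` edges inside planted topics.  Filler concepts are
  generated before the sense triples so that, in a degraded graph where
  all saliences tie, the CUI tie-break cannot favour topic concepts.
* **WSD datasets**: per instance, the gold sense is uniform over the
  candidates and each of the 20 context words comes from the gold
  sense's private definition vocabulary with probability *s*
  (separability) and from a disjoint confusion pool otherwise.  At
  *s* = 1 contexts are pure gold vocabulary; at *s* = 0 they carry no
  signal, so a deterministic tie-break yields chance accuracy.
* **Search corpus**: `docs_per_concept` equal-length documents per sense
  containing one monosemous synonym plus private vocabulary words —
  what the AEC queries are built to retrieve.  Equal lengths and counts
  keep the Naive Bayes priors and unseen-word likelihoods symmetric.
* **JD model**: one descriptor per semantic type whose word vector spans
  the vocabularies of that type's concepts (near-orthogonal across
  types), with a one-hot semantic-type index.
* **Documents**: `planted_topic_size` topic sentences mention the
  ambiguous term, the gold sense's parent and its partner sibling plus
  gold vocabulary; filler sentences mention an off-topic concept plus
  confusion words; all sentences have equal word counts, so the default
  compression of 0.30 with 3-of-10 topic sentences makes the reference
  exactly recoverable.  The reference summary is the topic sentences in
  document order.

Because vocabularies are disjoint and coded, passing tests demonstrate
correct mechanics and the direction of the WSD→summarization effect
under controlled conditions; they do not estimate absolute accuracies or
ROUGE levels on real biomedical text, where contexts overlap, MetaMap
candidate sets are noisier and reference summaries are abstracts rather
than extracted sentences.

## Numerical and degenerate-input choices

Cosine of an all-zero vector is 0.  Empty text preprocesses to an empty
vector.  An empty document, an empty candidate set, a zero-size cluster
or an accuracy over zero instances raise explicit errors.  Naive Bayes
invariants (priors and per-class likelihoods each exponentiating to 1)
hold to 1e-9.  Problem sizes in the automated checks — 500
oracle-comparison instances, 500-instance datasets per separability
level, 20 planted-topic documents, 100 random document graphs — were
chosen to make the binomial 3σ bands tight (≈ ±0.07 at chance 0.5)
while the whole suite runs in seconds.

## Known limitations

* No MetaMap variant generation or partial matching; dictionary
  longest-match is exact after normalization, and only English terms are
  handled.
* JD vectors must be supplied (or synthesized); there is no training
  path from MEDLINE citations.
* The RRF reader is a best-effort convenience covering only the columns
  the data model needs.
* Statistical significance testing between methods is not part of the
  package's scope; the evaluation tables expose per-document scores so
  any standard paired test can be applied downstream.
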