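# Methods

## The pipeline

`goqa` answers a natural-language question with ranked GO identifiers in
four stages.

**Question categorization.** A small rule table maps question scaffolds
("what molecular function(s) … of/affected by/associated with X",
"what cellular component … is the location of X", the biological-process
analogue) to a target namespace; the entity left over after removing the
scaffold becomes the retrieval query. The target namespace is the *target
set*: the only admissible answers. Unrecognized question forms raise an
error rather than guessing — a wrong target set silently poisons every
later stage.

**Retrieval.** An inverted index over title + abstract with Okapi BM25
scoring (k1 = 1.2, b = 0.75, the Okapi/Terrier convention). The idf is the
non-negative variant ln(1 + (N − df + 0.5)/(df + 0.5)); on the small
corpora this package targets, the classic signed idf can go negative for
tokens in more than half the documents, which makes scores unstable and
tie-breaking arbitrary. Ties break by ascending document id, so runs are
reproducible. A second mode, `boolean_recency`, keeps only documents
containing every query token and orders them newest-first; it stands in
for remote Boolean search engines ordered by reverse time. A remote
adapter would implement the same `search` contract; it is deliberately out
of scope. Stopword removal is applied identically to indexed text and
queries; stemming (a minimal plural stripper) exists behind a flag and is
off by default, since the classifiers compare like-normalized text on
both sides anyway.

**Per-abstract classification (micro-reading).** Two interchangeable
classifiers implement a common protocol `classify(text, namespace, m)`:

- *Dictionary.* Every non-obsolete term of the namespace becomes a
  pseudo-document containing its normalized name and all synonyms (all
  synonym scopes are indexed; scope is kept as metadata). A
  vector-space component ranks terms by BM25 with the abstract as the
  query — high recall, low precision. A pattern-matching component finds
  terms whose surface form occurs as a contiguous subsequence of the
  abstract's normalized tokens: no gaps, no reordering, no partial
  credit. This is a deliberately conservative reading of "lazy" pattern
  matching: it is reproducible and never hallucinates a match. Matched
  terms are boosted by B·match_length with B = 1 + max vsm score chosen
  per call, so any literal match outranks every unmatched candidate and
  longer matches outrank shorter ones. The boost is rank-dominant rather
  than a tuned constant because no principled magnitude exists: the
  ranking rule, not the number, is the model.
- *k-NN (supervised).* The knowledge base maps PMIDs to curated GO
  terms (read from GAF 2.x; rows with a NOT qualifier are negative
  assertions and are dropped; rows without a PMID reference cannot be
  literature-keyed and are dropped; the default evidence filter excludes
  IEA, i.e. keeps manually curated codes — the precise curated set is
  configurable because annotation practice varies between releases). The
  classifier retrieves the k = 100 knowledge-base abstracts most similar
  to the input (BM25), and scores each candidate term by its neighbour
  count ("most prevalent" voting). Zero-similarity documents are never
  neighbours. Ties break by summed neighbour similarity, then GO id.
  Similarity-weighted voting is available behind a flag but off by
  default; with count voting the vote is a property of curation, not of
  the retrieval engine's score scale. The *leave-out protocol* —
  `exclude_pmids` / `hold_out` — removes the classified documents from
  the neighbourhood so an abstract can never vote for itself.

Namespace filtering is applied *before* the per-document top-m cutoff
(m = 5 by default), so off-axis terms never consume answer slots.

**Aggregation (macro-reading).** A candidate's answer score is its
citation count: the number of retrieved abstracts whose top-m list
contains it, each PMID counted once. Sorting is count-descending, GO id
ascending. The conservation property Σ counts = Σ per-doc prediction-set
sizes holds by construction and is asserted in tests.

## Evaluation

Top Precision P0 = max over ranks i of |top-i ∩ gold|/i (interpolated
precision at recall 0; 0 for an empty list), Recall@r = |top-r ∩
gold|/|gold|. Matching is strict identifier equality after alt-id
resolution; hierarchical or semantic-similarity credit is explicitly not
given, so a gold term's child counts as wrong. Macro averages are
unweighted means over questions; questions with no answer set score 0
rather than being excluded, which keeps macro averages comparable between
systems. Significance between two systems is a two-sided paired sign-flip
randomization test on per-question differences, p = (1 + #{|permuted
mean| ≥ |observed|})/(1 + n_permutations), seeded. This is our choice of
test — the standard one for paired per-query IR metrics — not a
reproduction of any particular published analysis.

## Ontology conventions

Only `is_a` edges are modelled. Levels use the longest-path convention:
level(t) = number of edges on the longest is_a path from the namespace
root, root = 0. The phrase "number of nodes between term and root" is
ambiguous (off by one depending on whether endpoints count) and published
level figures depend on the ontology release, so levels here are defined
operationally and are monotone: level(child) = 1 + max over parents'
levels. Normalization is NFKC, lowercase, punctuation to whitespace except
hyphens and slashes (GO names contain "serine/threonine"), whitespace
collapsed.

## The synthetic generator

The generator emulates the statistical structure the method depends on,
not biomedical language. Token pools — background words, per-term *topic
tokens*, term-name tokens, entity names — are pairwise disjoint
pseudo-words derived deterministically from the seed. Each non-root term
receives `docs_per_term` curated abstracts (roots are not annotatable:
annotating the root of an axis conveys no information, mirroring curation
practice); each abstract carries 1–4 annotations, and its text mixes
background tokens, the topic tokens of every annotated term, and — with
probability ρ per annotation — the term's literal name spliced in as a
contiguous phrase. ρ is the generator's one scientifically load-bearing
dial: at ρ = 1 every annotation is on the page and a dictionary matcher
must find it; at ρ = 0 annotations are recoverable only through curated
data, the regime that motivates deep QA. The default ρ = 0.1.

QA benchmarks alternate molecular-function and cellular-component
questions (the chemical→function and protein→location styles). Each
entity receives `docs_per_entity` fresh, *un-annotated* documents (they
play the role of retrieved abstracts) containing the entity token and the
topic tokens of a random subset of its gold terms. Entity documents also
carry literal mentions of a few *general* terms — children of the
namespace root, mentioned with probability 0.3 each — mimicking the broad
vocabulary terms ("binding", "catalytic activity") that real abstracts
literally mention without their being the curated answer; published
dictionary-classifier output is dominated by exactly such spurious
matches. Distractor mentions are never drawn for gold terms, so the ρ
invariants above stay exact. General terms are likewise excluded from
gold sets: the curated answer to a specific question is essentially never
the axis's most generic vocabulary.

Default study conditions: 20 terms per namespace, 15 curated abstracts
per term (above the ~10 training examples per class usually considered
the minimum for supervised recovery), 2 synonyms and 6 topic tokens per
term, 200 background words, 30 questions with 1–3 gold answers and 20
entity documents each. One seed fixes every draw; ontology, corpus and
benchmark generation consume independent, labelled substreams of it, so
regenerating any one artifact is reproducible in isolation.

**What passing on synthetic data does and does not show.** Topic-token
disjointness makes lexical similarity an unrealistically clean signal:
real abstracts share vocabulary across concepts, have burstier word
distributions, and their curated terms are correlated with hierarchy
depth. Synthetic results therefore validate the *machinery and the
ordering of methods* (supervised ≥ dictionary when ρ is small; parity
when ρ = 1; insensitivity to the retrieval mode when entity documents are
few and all contain the entity token) — not absolute performance on
MEDLINE-scale corpora, which additionally requires a curated knowledge
base and live retrieval outside this package's scope.

## Numerical and degenerate-input choices

- Empty query after tokenization: error in `search`/`vsm_rank`; the QA
  pipeline treats a document that tokenizes to nothing as predicting
  nothing.
- Zero retrieved documents for a question: empty answer set with a
  warning, not an error — a benchmark run must not die on one entity.
- k larger than the knowledge base: clamp. Fewer than k positive-
  similarity neighbours: use those available.
- Duplicate ranked ids in evaluation: error (they would silently inflate
  P0).
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; there is no global random state.

## Problem sizes used in the shipped experiments

The acceptance checks run the core study at 30 questions over ~1500
documents (900 curated + 600 entity), the literal-mention micro benchmark
at 300 abstracts, and oracle-equivalence checks over 50 random knowledge
bases of up to 200 documents; the whole suite completes in seconds on one
CPU. These sizes give stable macro estimates (the deep-QA contrast ratio
exceeds its threshold by ~2× across seeds) while staying trivially cheap
to regenerate.

## Known limitations

- The question categorizer is a rule table covering the two benchmark
  templates plus close variants; open question forms are out of scope.
- Literal matching has no variant generation (abbreviations,
  morphological variants, approximate matches); that is faithful to the
  conservative pattern-matcher design, but real dictionary classifiers
  with variant generation would score between our two extremes.
- `boolean_recency` requires document dates and errors without them.
- GAF handling covers the columns the method uses (qualifier, GO id,
  reference, evidence); taxon constraints and annotation extensions are
  ignored.
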