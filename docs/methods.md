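# Methods

This note records the model behind the package, the rule sets and
parameters that matter, the numerical choices, and what the synthetic
corpora do and do not establish.

## The segment model

The indexing unit is the *maximal coherent semantic unit* (MCSU): the
largest span of a sentence carrying one coherent relation among
biomedical objects. Conventional indexes conflate all relations of a
document (or sentence); queries that name a relation and its arguments
then match text that never asserts the combination. Splitting at
relation boundaries and indexing the pieces keeps recall properties of
standard inverted indexing — the architecture is unchanged, segments
simply take the place of documents in the posting lists — while making
the context of each match semantically coherent.

A posting is `term -> (segment id, doc id, [object ids], [feature ids])`.
Only segments whose own span mentions at least one dictionary object are
indexed; relation features are optional. Carrying the object and feature
ids inside the posting is what lets query-time aggregation and the
object detail profiles run without revisiting the corpus.

## NLP layer

All linguistic processing is rule-based and deterministic, implemented
in `boss.nlp`:

- **Tokenizer**: regex-based; words keep internal hyphens, digits,
  slashes and apostrophes (`MS-1020`, `IL-8` are single tokens);
  punctuation becomes its own token; character offsets reconstruct the
  input exactly.
- **Sentence detector**: terminal `.!?` followed by whitespace and an
  upper-case letter, digit or opening quote ends a sentence, unless the
  preceding word is in a small abbreviation list (*et al.*, *Fig.*,
  *e.g.*); decimal points never split. The detector sits behind a plain
  function contract, so a statistical detector can be substituted.
- **POS tagger**: a left-to-right cascade — closed-class word lists,
  then a verb-form vocabulary (≈120 lemmas with generated inflections,
  covering the relation lexicon plus common scientific verbs) with a
  determiner-context veto (*a decrease* is a noun, *corticosteroids
  decrease* a verb), then suffix heuristics, defaulting to noun. The
  downstream logic needs reliable verb/noun/conjunction decisions on
  relation vocabulary, not full-coverage tagging, and the tagger is
  tuned for exactly that.
- **Morphology**: inflections are generated from lemmas (with a small
  irregular table: *bind→bound*, ...); derivational nominals are
  generated by affix rules (*inhibit→inhibitor/inhibition*,
  *activate→activator/activation*). Over-generated forms are harmless —
  they only act when the exact form occurs.

## Segmentation rules

The extraction cascade (in `boss.segmenter`), all over POS-tagged
tokens:

1. **Clause split** at: semicolons (kept with the left clause);
   subordinating conjunctions (*while, whereas, although, because,
   since, if, when*) with a verb on both sides; comma followed by a
   coordinating conjunction with a verb on both sides.
2. **Phrase split**: a clause containing two or more relation-trigger
   tokens is cut before each trigger after the first. The cut walks
   left from the trigger to a coordinating conjunction if one is
   reachable without crossing a verb or the preceding trigger — so
   *"...decrease CC chemokine **but** increase IL-8"* cuts at *but*, and
   *"...EGFR but TNF activates LIF"* also cuts at *but*, leaving the
   second segment its own subject. Splitting guarantees ≤ 1 trigger per
   segment. Trigger detection here uses the same predicate as feature
   annotation (verb forms and derivational nominals).
3. **Subject propagation**: a phrase-split segment that starts at a verb
   (ignoring leading conjunctions, commas, adverbs) has no subject of
   its own; the leading noun phrase of its left sibling (its tokens up
   to the first verb), or that sibling's own inherited subject, is
   copied into the segment's *matchable* text, rendered bracketed
   (`[Oral corticosteroids] but increase IL-8.`). Without this copy a
   query naming the shared subject could never retrieve the second
   relation. Token spans are untouched, so the segments of a sentence
   always partition its tokens exactly.

Segments of one sentence are therefore disjoint, covering, in sentence
order, and deterministic for identical input text.

## Annotation rules

- Object matching is greedy longest-match, left-to-right,
  non-overlapping, over normalized tokens of the matchable text
  (propagated subject included); multi-word surfaces are supported.
  Normalization case-folds, collapses whitespace and strips edge
  punctuation while preserving internal hyphens/digits.
- Short all-uppercase surfaces (≤ 5 characters) match case-sensitively;
  this is standard dictionary-NER hygiene against gene-symbol/function-
  word collisions (`WAS`, `IMPACT`).
- Duplicate surface forms across dictionary entries resolve to the
  first-seen entry with a logged warning (deterministic, order-stable).
- Feature mentions are taken only from the segment's own span — a
  trigger inside a propagated subject belongs to the sibling segment
  that contributed it.
- An object mention found inside the propagated subject makes the
  segment retrievable by that object's name but is not credited to the
  segment in the posting list, and does not by itself make the segment
  indexable; otherwise aggregation would double-count the subject
  across every split of its sentence.

## Scoring

`score_s(q, s) = coord(q, s) · Σ_f w(f) · Σ_o w(o) · rc`, and an
object's score is the plain sum over its matching segments.

- **coord**: fraction of query terms present in the segment's term set.
  A query term's alternate forms (original + lemma) count once.
- **Weights** `w(f)`, `w(o)`: non-negative, configurable per feature id
  / relation type and object id / object type; default uniform 1.0,
  reducing the sums to mention counts.
- **Recency** `rc = 2^(−Δ/h)`: Δ is query year minus publication year
  (clamped at 0; unknown years are neutral), `h` the half-life in
  years, default 10 — old enough that a decade-old article still
  carries half weight, which fits literature search. The functional
  form (exponential decay at year resolution) is this package's choice.
- **Empty feature sum**: the literal product zeroes featureless
  segments, but object-only segments are indexed on purpose; the
  default policy (`identity_one`) makes the empty feature factor 1, and
  `empty_feature_policy="zero"` restores the literal behavior.
- **Retrieval modes**: default is disjunctive (every segment with
  `coord > 0` is ranked, partial matches down-weighted by coord);
  `exact_context` keeps only `coord = 1` segments. Both are first-class
  because both behaviors are defensible readings of segment-exclusion
  semantics; neither is asserted as the only correct one.
- **Query time**: when not supplied, the newest publication year in the
  index is used, keeping results deterministic offline.

Numerical determinism: object scores are accumulated in segment-id
order, so summation order — and therefore every output bit — is
independent of hit ordering; ranking ties break by mention count then
object id (a total order).

## Synthetic corpora

`boss.fixtures` plants (subject, trigger, object) triples into templated
sentences — "X inhibited Y.", sometimes pairing two same-subject triples
into a compound "X inhibited Y but activated Z." that the segmenter must
split — interleaved with object-free distractor sentences, across
`n_docs` documents with seeded years. Defaults: years 2000–2011,
distractor rate 0 (tests use 0–0.4), all randomness from one seed.
Template vocabulary is restricted to the planted dictionary plus
closed-class filler, so annotation recall is 1.0 by construction and
expected mention/article counts per object are known exactly (a
compound sentence credits the shared subject to its first segment only,
matching the posting rule above).

What passing proves: the segmentation, annotation, indexing and scoring
machinery is exact on text whose structure is known. What it does not
prove: tagger and dictionary robustness on real biomedical prose —
free-text abstracts contain parentheticals, anaphora, nested clauses
and ambiguous symbols that the generator deliberately does not emulate.

Test and acceptance problem sizes — tens of documents and at most ~100
segments per corpus, 50 seeded corpora per property run — are chosen as
desk-scale: large enough to exercise every code path (compound splits,
distractors, multi-word names, year spread), small enough that
brute-force oracles stay trivially exact.

## Verification strategy

- Golden tests pin the two worked sentences (segment counts, mention
  counts, the NEGATIVE/inhibit feature, the IL-8 / CC-chemokine
  retrieval asymmetry, the zero-hit split-keyword query).
- The retrieval path is checked against a brute-force oracle that
  linearly scans every stored segment and recomputes the score from the
  defining formulas, requiring exact equality of the full ranked output.
- Planted-truth recovery requires exact mention/article counts across
  seeded corpora.
- Property tests cover normalization idempotence, token-coverage of
  segmentation, the ≤ 1-trigger post-split ceiling, posting
  completeness/soundness against segment term sets, document-order
  invariance of the index, and persistence round-trips.

## Known limitations

- The rule tagger's verb vocabulary is finite; relation verbs outside
  it (and outside the lexicon) are invisible to segmentation, and
  `derive_features_from_corpus` undercounts verbs it cannot tag.
- Clause rules do not handle relative clauses, parentheticals, or
  coordination without a comma/conjunction signal.
- Subject propagation copies only the same-sentence left sibling's
  leading noun phrase; no anaphora resolution.
- No disambiguation between objects sharing a surface form, no species
  resolution, no learned ranking; scoring-quality evaluation is out of
  scope.
- The single-file JSON index targets desk-scale corpora (up to roughly
  10^5 segments), not web-scale sharded deployment.
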