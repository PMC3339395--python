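# boss-search

Entity-centric search over biomedical abstracts. Instead of returning a
list of documents for a query, the engine returns a ranked list of
**biomedical objects** — genes, proteins, drugs, diseases — each backed
by the text evidence that matched.

The core idea is the indexing unit. A sentence such as

> *Oral corticosteroids decrease CC chemokine but increase IL-8.*

holds two contradicting relations. A document-level (or even
sentence-level) index would return this text for the query *"decrease
IL-8"*, which it does not actually assert. This engine splits every
sentence into **maximal coherent semantic units** (MCSUs, "segments") —
the largest spans carrying one coherent relation — and indexes those.
The sentence above becomes two segments; *"oral corticosteroids
increase"* then retrieves IL-8 and only IL-8, while *"decrease IL-8"*
matches no segment at all.

## Method

**Lexicons.** Objects come from a user-supplied dictionary (TSV or
JSON-lines: id, name, synonyms, type), matched longest-match-first over
normalized tokens, with case-sensitive matching for short all-uppercase
symbols (so the gene `WAS` never matches the verb *was*). Relations come
from a bundled lexicon of 51 trigger-verb lemmas in 10 relation types
(NEGATIVE, FULL-STOP, BREAK-DOWN, DECREASE, INCREASE, START, ADDITION,
ASSEMBLY, UNSPECIFIED, POSITIVE). Inflections (*inhibited*) and
derivational nominals (*inhibitors*, *inhibition*) resolve to their
lemma, so the query *"EGFR inhibitors"* finds segments saying
*...inhibits EGFR...*. `derive_features_from_corpus` ranks candidate
trigger verbs in a new corpus by frequency for lexicon extension.

**Segmentation.** Sentences are split by an abbreviation-aware rule
detector, POS-tagged by a deterministic rule tagger, cut into clauses
(semicolons; subordinating conjunctions and comma+conjunction with a
verb on both sides), and each clause holding ≥ 2 relation triggers is
cut again before each extra trigger, preferring a coordinating
conjunction as the cut point. A split segment starting at a verb
inherits its left sibling's subject noun phrase into its matchable text
(rendered bracketed: `[Oral corticosteroids] but increase IL-8.`), so it
remains retrievable by subject terms.

**Index.** Only segments mentioning at least one object are indexed.
Each posting carries the segment's object ids and feature ids
(`term -> [(segment, doc, [objects], [features])]`), so results
aggregate per object without revisiting the corpus.

**Scoring.** A matching segment *s* for query *q* scores

```
score_s(q, s) = coord(q, s) · Σ_f w(f) · Σ_o w(o) · rc
```

where `coord` is the fraction of query terms present in *s*, the sums
run over the segment's features and objects (weights default to 1.0, so
the sums are counts), and `rc = 2^(−Δyears / half-life)` decays with the
age of the source article (half-life 10 years by default). An object's
score is the sum of its matching segments' scores; objects are ranked by
score, ties by mention count, then id. `--exact-context` restricts
retrieval to segments containing **all** query terms (`coord = 1`).

## Worked example

```
$ cat objects.tsv
O_MS1020	MS-1020
O_STAT3	STAT3		protein
O_CORT	oral corticosteroids		drug
O_CCCHEM	CC chemokine		protein
O_IL8	IL-8		protein

$ cat corpus.jsonl
{"id": "PM1", "year": 2011, "text": "Oral corticosteroids decrease CC chemokine but increase IL-8. MS-1020 potently inhibited persistently-active STAT3."}

$ boss index --corpus corpus.jsonl --objects objects.tsv --out demo.index.json
indexed 3 segments from 1 documents

$ boss search --index demo.index.json --query "oral corticosteroids increase" --exact-context
1. IL-8 [O_IL8]  score=1.0000  1 mentions in 1 articles
     (PM1) [Oral corticosteroids] but increase IL-8.

$ boss search --index demo.index.json --query "STAT3 inhibitors"
1. MS-1020 [O_MS1020]  score=2.0000  1 mentions in 1 articles
     (PM1) MS-1020 potently inhibited persistently-active STAT3.
2. STAT3 [O_STAT3]  score=2.0000  1 mentions in 1 articles
     (PM1) MS-1020 potently inhibited persistently-active STAT3.
```

The first query matches only the second segment of the contradicting
sentence: IL-8 is returned, CC chemokine is not, and its score is
`coord 1.0 × 1 feature × 1 object × rc 1.0 = 1.0`. The second query
shows nominal-to-lemma resolution: *inhibitors* hits the inflected verb
*inhibited*; the matching segment holds one feature and two objects, so
each object scores `1.0 × 1 × 2 × 1.0 = 2.0` (MS-1020 ranks first by the
id tie-break). `boss object --index demo.index.json --id O_IL8` prints
the detail profile: articles per year, the interaction cloud, and
co-occurring objects; `boss generate` emits seeded synthetic corpora
with planted ground truth for testing.

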