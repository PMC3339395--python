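"""Shared fixtures: lexicons, worked-example indexes, random corpora, oracle."""

from __future__ import annotations

import random

import pytest

from boss import fixtures, indexer, lexicon, search

OBJECT_NAME_POOL = [
    "STAT3", "EGFR", "TNF", "CSF3", "BRCA1", "TP53", "AKT1", "LIF",
    "cytarabine", "erythropoietin", "oral corticosteroids", "CC chemokine",
]


@pytest.fixture(scope="session")
def feature_lexicon():
    return lexicon.load_feature_lexicon()


@pytest.fixture(scope="session")
def paper_bundle():
    return fixtures.paper_fixtures()


@pytest.fixture(scope="session")
def example2_index(paper_bundle, feature_lexicon):
    """Index over the single contradicting-relations worked sentence."""
    corpus = [{"id": "d2", "year": 2011, "text": paper_bundle.example2}]
    return indexer.build_index(corpus, paper_bundle.dictionary, feature_lexicon)


def random_corpus_spec(seed: int, lemmas: list[str]) -> fixtures.CorpusSpec:
    """A small randomized corpus spec, deterministic in ``seed``."""
    rng = random.Random(seed * 7919 + 17)
    objs = rng.sample(OBJECT_NAME_POOL, rng.randint(4, 8))
    templates = []
    for _ in range(rng.randint(2, 6)):
        subject, obj = rng.sample(objs, 2)
        templates.append(
            fixtures.RelationTemplate(
                subject, rng.choice(lemmas), obj, rng.randint(1, 3)
            )
        )
    return fixtures.CorpusSpec(
        n_docs=rng.randint(2, 6),
        objects=objs,
        relation_templates=templates,
        distractor_rate=rng.choice([0.0, 0.2, 0.4]),
        seed=seed,
    )


def build_random_index(seed: int, feature_lexicon):
    spec = random_corpus_spec(seed, [e.lemma for e in feature_lexicon])
    docs, truth = fixtures.generate_corpus(spec)
    dictionary = spec.object_dictionary()
    index = indexer.build_index(docs, dictionary, feature_lexicon)
    return spec, docs, truth, dictionary, index


def brute_force_ranking(
    index: indexer.SegmentIndex,
    query: search.Query,
    config: search.ScoringConfig | None = None,
    exact_context: bool = False,
):
    """Score every stored segment directly from the defining formulas.

    Independent of the index-probing path: linearly scans the segment
    store, recomputes the coordination fraction from term sets, the
    weight sums, the recency decay, multiplies, sums per object, and
    sorts with the same total order.  Returns comparable tuples.
    """
    config = config or search.ScoringConfig()
    years = [d["year"] for d in index.docs.values() if d.get("year") is not None]
    query_time = query.query_time if query.query_time is not None else (
        max(years) if years else None
    )
    per_object: dict[str, dict] = {}
    for sid in index.segments:
        record = index.segments[sid]
        present = sum(
            1 for term in query.terms if term.alternates & record.terms
        )
        c = present / len(query.terms)
        if c == 0.0 or (exact_context and c < 1.0):
            continue
        fsum = sum(config.feature_weight(f, index) for f in record.feature_ids)
        ffactor = fsum if record.feature_ids else (
            1.0 if config.empty_feature_policy == "identity_one" else 0.0
        )
        osum = sum(config.object_weight(o, index) for o in record.object_ids)
        if record.year is None or query_time is None:
            rc = 1.0
        else:
            rc = 2.0 ** (-max(0, query_time - record.year) / config.recency_half_life)
        score = c * ffactor * osum * rc
        for oid in record.object_ids:
            acc = per_object.setdefault(oid, {"score": 0.0, "n": 0, "docs": set()})
            acc["score"] += score
            acc["n"] += 1
            acc["docs"].add(record.doc_id)
    rows = [
        (oid, acc["score"], acc["n"], len(acc["docs"]))
        for oid, acc in per_object.items()
    ]
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows
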