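"""Query execution: segment scoring, object aggregation, ranking, profiles.

A free-text query retrieves the union of posting lists over its terms.
Each candidate segment ``s`` is scored as the product

    score_s(q, s) = coord(q, s) x sum_f w(f) x sum_o w(o) x rc

where ``coord`` is the fraction of query terms the segment contains,
the sums run over the relation features and objects of the segment with
non-negative configurable weights (uniform 1.0 by default, reducing the
sums to counts), and ``rc`` is a recency factor decaying exponentially
with the age of the source article at query time.  An object's score is
the plain sum of the scores of the matching segments that mention it.

Two retrieval modes: the default ranks every segment with ``coord > 0``;
*exact-context* mode keeps only segments containing **all** query terms
(``coord = 1``), so a query whose terms never co-occur inside one
segment returns nothing even when each term matches somewhere.

A segment with no relation feature would score zero under the literal
product; because object-only segments are indexed on purpose, the
default policy replaces the empty feature sum by 1 (``identity_one``);
``zero`` gives the literal behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyQueryError, ObjectNotFoundError
from .indexer import SegmentIndex, SegmentRecord, joined_surface_term
from .lexicon import FeatureLexicon, load_feature_lexicon, normalize_surface
from .nlp import STOPWORDS, tokenize


@dataclass(frozen=True)
class QueryTerm:
    """One query term with its acceptable alternate forms.

    A nominal or inflected relation trigger ("inhibitors") keeps the
    original form and gains the lexicon lemma as an alternate; the
    alternates of one term count once in the coordination factor.
    """

    text: str
    alternates: frozenset[str]


@dataclass
class Query:
    raw: str
    terms: list[QueryTerm]
    query_time: int | None = None


@dataclass
class ScoringConfig:
    """Weights and policies entering the segment score.

    ``feature_weights`` / ``object_weights`` map a feature id or
    relation type (resp. object id or object type) to a non-negative
    weight; anything unlisted weighs 1.0.  ``recency_half_life`` is in
    years.
    """

    feature_weights: dict[str, float] = field(default_factory=dict)
    object_weights: dict[str, float] = field(default_factory=dict)
    recency_half_life: float = 10.0
    empty_feature_policy: str = "identity_one"  # identity_one | zero

    def __post_init__(self):
        if self.recency_half_life <= 0:
            raise ValueError("recency_half_life must be positive")
        if self.empty_feature_policy not in ("identity_one", "zero"):
            raise ValueError(
                f"unknown empty_feature_policy {self.empty_feature_policy!r}"
            )
        for table in (self.feature_weights, self.object_weights):
            for key, value in table.items():
                if not (value >= 0):
                    raise ValueError(f"weight for {key!r} must be >= 0")

    def feature_weight(self, feature_id: str, index: SegmentIndex) -> float:
        if feature_id in self.feature_weights:
            return self.feature_weights[feature_id]
        meta = index.features.get(feature_id, {})
        return self.feature_weights.get(meta.get("relation_type"), 1.0)

    def object_weight(self, object_id: str, index: SegmentIndex) -> float:
        if object_id in self.object_weights:
            return self.object_weights[object_id]
        meta = index.objects.get(object_id, {})
        return self.object_weights.get(meta.get("type"), 1.0)


@dataclass(frozen=True)
class SegmentHit:
    """A scored segment with the components of its score."""

    segment_id: str
    coord: float
    feature_sum: float
    object_sum: float
    rc: float
    score: float


@dataclass
class ObjectResult:
    """Aggregated result for one object."""

    object_id: str
    score: float
    mention_count: int
    article_count: int
    snippets: list[tuple[str, str]]  # (doc_id, segment text), at most 5
    name: str = ""

SNIPPET_COUNT = 5


# --------------------------------------------------------------------------
# Query parsing
# --------------------------------------------------------------------------

def parse_query(
    raw: str,
    query_time: int | None = None,
    lexicon: FeatureLexicon | None = None,
) -> Query:
    """Tokenize, normalize and stopword-filter a free-text query.

    Double-quoted phrases become single terms matching the joined form
    under which multi-word object surfaces are indexed.  A query left
    with no terms is an error.
    """
    if lexicon is None:
        lexicon = load_feature_lexicon()
    terms: list[QueryTerm] = []
    remainder = []
    pieces = raw.split('"')
    for i, piece in enumerate(pieces):
        if i % 2 == 1 and piece.strip():
            joined = joined_surface_term(piece)
            if joined:
                terms.append(QueryTerm(piece.strip(), frozenset({joined})))
        else:
            remainder.append(piece)
    for token in tokenize(" ".join(remainder)):
        norm = normalize_surface(token.surface)
        if not norm or norm in STOPWORDS:
            continue
        alternates = {norm}
        entry = lexicon.match_any_form(norm)
        if entry is not None:
            alternates.add(entry.lemma)
        terms.append(QueryTerm(norm, frozenset(alternates)))
    if not terms:
        raise EmptyQueryError(f"query {raw!r} has no searchable terms")
    return Query(raw=raw, terms=terms, query_time=query_time)


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def coord(query: Query, segment_terms: frozenset[str]) -> float:
    """Fraction of query terms present in the segment's term set."""
    present = sum(
        1 for term in query.terms if term.alternates & segment_terms
    )
    return present / len(query.terms)


def recency(
    publication_year: int | None,
    query_time: int | None,
    config: ScoringConfig,
) -> float:
    """Exponential half-life decay in the article's age, in (0, 1].

    Unknown years and future-dated articles clamp to age zero.
    """
    if publication_year is None or query_time is None:
        return 1.0
    delta = max(0, query_time - publication_year)
    return 2.0 ** (-delta / config.recency_half_life)


def _resolve_query_time(query: Query, index: SegmentIndex) -> int | None:
    if query.query_time is not None:
        return query.query_time
    years = [d["year"] for d in index.docs.values() if d.get("year") is not None]
    return max(years) if years else None


def score_segment(
    query: Query,
    record: SegmentRecord,
    config: ScoringConfig,
    index: SegmentIndex,
    query_time: int | None = None,
) -> SegmentHit:
    """Score one indexed segment against the query."""
    c = coord(query, record.terms)
    feature_sum = sum(
        config.feature_weight(fid, index) for fid in record.feature_ids
    )
    if record.feature_ids:
        feature_factor = feature_sum
    else:
        feature_factor = 1.0 if config.empty_feature_policy == "identity_one" else 0.0
    object_sum = sum(
        config.object_weight(oid, index) for oid in record.object_ids
    )
    rc = recency(record.year, query_time, config)
    return SegmentHit(
        segment_id=record.segment_id,
        coord=c,
        feature_sum=feature_sum,
        object_sum=object_sum,
        rc=rc,
        score=c * feature_factor * object_sum * rc,
    )


def match_segments(
    index: SegmentIndex,
    query: Query,
    config: ScoringConfig | None = None,
    exact_context: bool = False,
) -> list[SegmentHit]:
    """Retrieve and score the segments matching a query.

    Disjunctive by default (every segment sharing at least one term with
    the query is scored); ``exact_context`` keeps only segments holding
    all query terms.  Hits are sorted by score, ties by segment id.
    """
    config = config or ScoringConfig()
    query_time = _resolve_query_time(query, index)
    candidates: set[str] = set()
    for term in query.terms:
        for alternate in term.alternates:
            candidates.update(index.postings.get(alternate, ()))
    hits = []
    for sid in sorted(candidates):
        hit = score_segment(query, index.segments[sid], config, index, query_time)
        if hit.coord <= 0.0:
            continue
        if exact_context and hit.coord < 1.0:
            continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.segment_id))
    return hits


def aggregate_objects(
    hits: list[SegmentHit], index: SegmentIndex
) -> list[ObjectResult]:
    """Fold segment hits into one result per object they mention.

    A segment's full score is credited to every object it contains.
    Snippets are the object's top-five segments by score.  Scores are
    accumulated in segment-id order so the sums are bit-reproducible
    regardless of hit ordering.
    """
    per_object: dict[str, dict] = {}
    for hit in sorted(hits, key=lambda h: h.segment_id):
        record = index.segments[hit.segment_id]
        for object_id in record.object_ids:
            acc = per_object.setdefault(
                object_id, {"score": 0.0, "segments": [], "docs": set()}
            )
            acc["score"] += hit.score
            acc["segments"].append((hit, record))
            acc["docs"].add(record.doc_id)
    results = []
    for object_id, acc in per_object.items():
        top = sorted(
            acc["segments"], key=lambda pair: (-pair[0].score, pair[0].segment_id)
        )[:SNIPPET_COUNT]
        results.append(
            ObjectResult(
                object_id=object_id,
                score=acc["score"],
                mention_count=len(acc["segments"]),
                article_count=len(acc["docs"]),
                snippets=[(rec.doc_id, rec.text) for _, rec in top],
                name=index.objects.get(object_id, {}).get("name", object_id),
            )
        )
    return results


def rank_objects(results: list[ObjectResult]) -> list[ObjectResult]:
    """Descending score; ties by mention count, then object id."""
    return sorted(
        results, key=lambda r: (-r.score, -r.mention_count, r.object_id)
    )


def run_query(
    index: SegmentIndex,
    raw: str,
    config: ScoringConfig | None = None,
    exact_context: bool = False,
    query_time: int | None = None,
    lexicon: FeatureLexicon | None = None,
) -> list[ObjectResult]:
    """Parse, match, aggregate and rank in one call."""
    query = parse_query(raw, query_time=query_time, lexicon=lexicon)
    hits = match_segments(index, query, config=config, exact_context=exact_context)
    return rank_objects(aggregate_objects(hits, index))


# --------------------------------------------------------------------------
# Object detail profiles
# --------------------------------------------------------------------------

@dataclass
class ObjectProfile:
    """Detail-page statistics for one object, possibly query-scoped."""

    object_id: str
    name: str
    segment_count: int
    article_count: int
    per_year: dict[int, int]            # year -> distinct articles
    interactions: list[tuple[str, int]]  # feature lemma -> segment count
    co_objects: list[tuple[str, int]]    # co-occurring object -> segment count


def object_profile(
    index: SegmentIndex,
    object_id: str,
    context: Query | None = None,
    co_object: str | None = None,
    feature: str | None = None,
    config: ScoringConfig | None = None,
) -> ObjectProfile:
    """Statistics over the segments mentioning an object.

    With ``context`` the segments are restricted to those matching the
    query (any term overlap); ``co_object`` keeps segments also
    mentioning that object; ``feature`` (a lexicon lemma or feature id)
    keeps segments carrying that relation.  An object absent from the
    index metadata is an error; an object with no qualifying segments
    yields an empty profile.
    """
    if object_id not in index.objects:
        raise ObjectNotFoundError(f"unknown object id {object_id!r}")
    feature_ids: set[str] | None = None
    if feature is not None:
        feature_ids = {
            fid
            for fid, meta in index.features.items()
            if fid == feature or meta["lemma"] == feature
        }
    docs_per_year: dict[int, set[str]] = {}
    interactions: dict[str, int] = {}
    co_counts: dict[str, int] = {}
    segment_count = 0
    articles: set[str] = set()
    for record in index.segments.values():
        if object_id not in record.object_ids:
            continue
        if context is not None and coord(context, record.terms) <= 0.0:
            continue
        if co_object is not None and co_object not in record.object_ids:
            continue
        if feature_ids is not None and not feature_ids.intersection(
            record.feature_ids
        ):
            continue
        segment_count += 1
        articles.add(record.doc_id)
        if record.year is not None:
            docs_per_year.setdefault(record.year, set()).add(record.doc_id)
        for fid in record.feature_ids:
            lemma = index.features[fid]["lemma"]
            interactions[lemma] = interactions.get(lemma, 0) + 1
        for other in record.object_ids:
            if other != object_id:
                co_counts[other] = co_counts.get(other, 0) + 1
    return ObjectProfile(
        object_id=object_id,
        name=index.objects[object_id].get("name", object_id),
        segment_count=segment_count,
        article_count=len(articles),
        per_year={y: len(ds) for y, ds in sorted(docs_per_year.items())},
        interactions=sorted(interactions.items(), key=lambda kv: (-kv[1], kv[0])),
        co_objects=sorted(co_counts.items(), key=lambda kv: (-kv[1], kv[0])),
    )
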