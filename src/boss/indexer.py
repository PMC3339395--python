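"""Segment-level inverted index with object/feature-annotated postings.

The engine treats segments (MCSUs) the way a conventional search engine
treats documents: every content term of a segment's matchable text posts
to that segment, and each posting carries the ids of the objects and
relation features the segment mentions, so results can be aggregated per
object at query time without touching the corpus again.

Term universe of a segment: the normalized unigrams of its matchable
text minus a small stopword list, plus the lemma of every matched
relation trigger (so ``inhibited`` is findable as ``inhibit``), plus a
joined form of every multi-word object surface (``oral_corticosteroids``)
for precise phrase queries.  Relation trigger tokens are never
stopworded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from . import annotator, segmenter
from .errors import IndexCorruptionError, IndexVersionError, InputError
from .lexicon import FeatureLexicon, ObjectDictionary, normalize_surface
from .nlp import STOPWORDS

logger = logging.getLogger(__name__)

INDEX_FORMAT = "boss-index"
INDEX_VERSION = 1


@dataclass(frozen=True)
class PostingEntry:
    """One posting: a segment with its objects and features."""

    segment_id: str
    doc_id: str
    object_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]


@dataclass
class SegmentRecord:
    """Stored per-segment payload backing postings and snippets."""

    segment_id: str
    doc_id: str
    year: int | None
    text: str
    terms: frozenset[str]
    object_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]


@dataclass
class SegmentIndex:
    """Inverted index over segments plus object/feature metadata."""

    postings: dict[str, list[str]] = field(default_factory=dict)
    segments: dict[str, SegmentRecord] = field(default_factory=dict)
    docs: dict[str, dict] = field(default_factory=dict)
    objects: dict[str, dict] = field(default_factory=dict)
    features: dict[str, dict] = field(default_factory=dict)
    skipped_records: int = 0

    def __len__(self) -> int:
        return len(self.segments)


def joined_surface_term(surface: str) -> str:
    """Indexable single-term form of a multi-word surface."""
    return "_".join(normalize_surface(surface).split())


def segment_terms(
    segment: segmenter.Segment,
    lexicon: FeatureLexicon,
    stopwords: frozenset[str] = STOPWORDS,
) -> set[str]:
    """Term set of a segment's matchable text.

    Stopwords are dropped unless the token is a relation trigger; each
    trigger also posts under its lemma; multi-word object mentions post
    under a joined form of the matched surface.
    """
    terms: set[str] = set()
    feature_indices = {m.token_index for m in segment.feature_mentions}
    for index, (surface, _tag) in enumerate(segment.matchable_tokens):
        own_index = index - segment.n_subject_tokens
        norm = normalize_surface(surface)
        if not norm:
            continue
        if norm in stopwords and own_index not in feature_indices:
            continue
        terms.add(norm)
    for mention in segment.feature_mentions:
        entry = lexicon.by_id[mention.feature_id]
        terms.add(entry.lemma)
    for mention in segment.object_mentions:
        if mention.token_span[1] - mention.token_span[0] > 1:
            terms.add(joined_surface_term(mention.surface))
    return terms


def _ordered_unique(ids: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for i in ids:
        seen.setdefault(i)
    return tuple(seen)


def build_index(
    corpus: Iterable,
    dictionary: ObjectDictionary,
    lexicon: FeatureLexicon,
    config=None,
) -> SegmentIndex:
    """Index a corpus of abstracts.

    ``corpus`` yields mappings with keys ``id``, ``year`` (optional) and
    ``text``.  Unreadable records are logged, counted and skipped.  The
    pipeline per document: sentence split -> MCSU extraction -> object &
    feature annotation -> indexability filter -> postings.  Segment ids
    are ``{doc}:{sent}:{ordinal}``, so the final index is independent of
    document order.
    """
    stopwords = getattr(config, "stopwords", None) or STOPWORDS
    index = SegmentIndex()
    for entry in dictionary:
        index.objects[entry.object_id] = {
            "name": entry.canonical_name,
            "type": entry.object_type,
        }
    for feature in lexicon:
        index.features[feature.feature_id] = {
            "lemma": feature.lemma,
            "relation_type": feature.relation_type,
        }
    for record in corpus:
        try:
            doc_id = str(record["id"])
            text = record["text"]
            year = record.get("year")
            year = int(year) if year is not None else None
        except (TypeError, KeyError, ValueError) as exc:
            logger.warning("skipping unreadable corpus record: %s", exc)
            index.skipped_records += 1
            continue
        index.docs[doc_id] = {"year": year}
        for sentence in segmenter.split_sentences(text, doc_id=doc_id):
            segmenter.pos_tag(sentence)
            for segment in segmenter.extract_mcsus(sentence, lexicon):
                annotator.annotate_objects(segment, dictionary)
                annotator.annotate_features(segment, lexicon)
                if not annotator.is_indexable(segment):
                    continue
                terms = segment_terms(segment, lexicon, stopwords)
                rec = SegmentRecord(
                    segment_id=segment.segment_id,
                    doc_id=doc_id,
                    year=year,
                    text=segment.matchable_text,
                    terms=frozenset(terms),
                    object_ids=_ordered_unique(
                        m.object_id
                        for m in segment.object_mentions
                        if not m.in_subject
                    ),
                    feature_ids=_ordered_unique(
                        m.feature_id for m in segment.feature_mentions
                    ),
                )
                index.segments[rec.segment_id] = rec
                for term in terms:
                    index.postings.setdefault(term, []).append(rec.segment_id)
    for term in index.postings:
        index.postings[term] = sorted(set(index.postings[term]))
    index.postings = dict(sorted(index.postings.items()))
    index.segments = dict(sorted(index.segments.items()))
    return index


def lookup(index: SegmentIndex, term: str) -> list[PostingEntry]:
    """Posting list of a term (empty for unknown terms, never an error)."""
    sids = index.postings.get(normalize_surface(term), [])
    return [
        PostingEntry(
            segment_id=sid,
            doc_id=index.segments[sid].doc_id,
            object_ids=index.segments[sid].object_ids,
            feature_ids=index.segments[sid].feature_ids,
        )
        for sid in sids
    ]


def save_index(index: SegmentIndex, path) -> None:
    """Persist the index as a single versioned JSON container."""
    payload = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "postings": index.postings,
        "segments": {
            sid: {
                "doc_id": rec.doc_id,
                "year": rec.year,
                "text": rec.text,
                "terms": sorted(rec.terms),
                "object_ids": list(rec.object_ids),
                "feature_ids": list(rec.feature_ids),
            }
            for sid, rec in index.segments.items()
        },
        "docs": index.docs,
        "objects": index.objects,
        "features": index.features,
    }
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, sort_keys=True), encoding="utf-8"
    )


def load_index(path) -> SegmentIndex:
    """Reload a persisted index; ``load(save(x))`` is identity."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"index file not found: {p}")
    try:
        payload = json.loads(p.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexCorruptionError(f"cannot parse index file {p}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != INDEX_FORMAT:
        raise IndexCorruptionError(f"{p} is not a {INDEX_FORMAT} file")
    if payload.get("version") != INDEX_VERSION:
        raise IndexVersionError(
            f"{p}: format version {payload.get('version')!r}, "
            f"expected {INDEX_VERSION}"
        )
    try:
        index = SegmentIndex(
            postings={t: list(sids) for t, sids in payload["postings"].items()},
            docs=payload["docs"],
            objects=payload["objects"],
            features=payload["features"],
        )
        for sid, rec in payload["segments"].items():
            index.segments[sid] = SegmentRecord(
                segment_id=sid,
                doc_id=rec["doc_id"],
                year=rec["year"],
                text=rec["text"],
                terms=frozenset(rec["terms"]),
                object_ids=tuple(rec["object_ids"]),
                feature_ids=tuple(rec["feature_ids"]),
            )
    except (KeyError, TypeError) as exc:
        raise IndexCorruptionError(f"{p}: missing index payload field: {exc}") from exc
    return index
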