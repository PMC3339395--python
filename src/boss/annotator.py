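"""Object and feature mention detection inside segments.

Object mentions come from longest-match-wins, left-to-right dictionary
matching over normalized tokens of the segment's matchable text
(propagated subject included, multi-word surfaces supported).  Feature
mentions come from matching each POS-tagged token of the segment's own
span against the relation lexicon — tokens copied in from a propagated
subject never yield feature mentions.

Only segments carrying at least one object are worth indexing; features
are optional.  A mention found inside the propagated subject makes the
object *searchable* in that segment but does not, by itself, make the
segment indexable, nor is the object credited to the segment in the
posting list: the segment's own span must mention an object.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lexicon import FeatureLexicon, ObjectDictionary, normalize_surface
from .segmenter import Segment


@dataclass(frozen=True)
class ObjectMention:
    """A dictionary object matched in a segment's matchable text."""

    object_id: str
    segment_id: str
    surface: str
    token_span: tuple[int, int]  # over matchable tokens (subject first)
    in_subject: bool = False


@dataclass(frozen=True)
class FeatureMention:
    """A relation trigger matched in a segment's own span."""

    feature_id: str
    segment_id: str
    surface: str
    token_index: int  # over the segment's own tokens


def _max_surface_tokens(dictionary: ObjectDictionary) -> int:
    longest = 1
    for key in dictionary.surface_index:
        longest = max(longest, len(key.split()))
    return longest


def annotate_objects(
    segment: Segment, dictionary: ObjectDictionary
) -> list[ObjectMention]:
    """Detect object mentions, longest match first, left to right.

    Matches are non-overlapping and ordered by position.  Short
    all-uppercase dictionary surfaces (gene symbols) match
    case-sensitively; everything else matches on the normalized form.
    """
    tokens = segment.matchable_tokens
    n_subject = segment.n_subject_tokens
    normalized = [normalize_surface(surface) for surface, _ in tokens]
    longest = _max_surface_tokens(dictionary)
    mentions: list[ObjectMention] = []
    i = 0
    while i < len(tokens):
        if not normalized[i]:
            i += 1
            continue
        matched = None
        for n in range(min(longest, len(tokens) - i), 0, -1):
            window = normalized[i : i + n]
            if any(not w for w in window):
                continue
            raw = " ".join(tokens[j][0] for j in range(i, i + n))
            entry = dictionary.lookup(raw)
            if entry is not None and normalize_surface(raw) == " ".join(window):
                matched = (entry, n, raw)
                break
        if matched is None:
            i += 1
            continue
        entry, n, raw = matched
        mentions.append(
            ObjectMention(
                object_id=entry.object_id,
                segment_id=segment.segment_id,
                surface=raw,
                token_span=(i, i + n),
                in_subject=(i + n) <= n_subject,
            )
        )
        i += n
    segment.object_mentions = mentions
    return mentions


def annotate_features(
    segment: Segment, lexicon: FeatureLexicon
) -> list[FeatureMention]:
    """Detect relation triggers among the segment's own tagged tokens."""
    mentions: list[FeatureMention] = []
    for index, (surface, tag) in enumerate(segment.tokens):
        entry = lexicon.match(surface, tag)
        if entry is not None:
            mentions.append(
                FeatureMention(
                    feature_id=entry.feature_id,
                    segment_id=segment.segment_id,
                    surface=surface,
                    token_index=index,
                )
            )
    segment.feature_mentions = mentions
    return mentions


def is_indexable(segment: Segment) -> bool:
    """True iff the segment's own span mentions at least one object."""
    return any(not m.in_subject for m in segment.object_mentions)
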