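"""Sentence splitting and extraction of maximal coherent semantic units.

A *maximal coherent semantic unit* (MCSU, "segment") is the largest
stretch of a sentence that carries one coherent relation.  The sentence
"Oral corticosteroids decrease CC chemokine but increase IL-8" holds two
contradicting relations and therefore yields two segments; indexing at
this granularity is what lets a query like "oral corticosteroids
increase" retrieve IL-8 but not CC chemokine.

Extraction is a two-stage rule cascade over POS-tagged tokens:

1. **clause split** — at semicolons, at subordinating conjunctions
   (while, whereas, although, because, since, if, when) with a verb on
   both sides, and at comma + coordinating conjunction with a verb on
   both sides;
2. **phrase split** — a clause holding two or more relation trigger
   words is cut before each trigger after the first, preferring a cut
   at an intervening coordinating conjunction (absorbed into the right
   span), until every span holds at most one trigger.

A split span that starts at a verb has no subject of its own; the
subject noun phrase of its left sibling is copied into its *matchable*
text so the segment stays self-contained for retrieval.  Token spans are
untouched by this copy, so the segments of a sentence always partition
its tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import nlp
from .lexicon import FeatureLexicon

_CLAUSE_SUBORDINATORS = nlp.SUBORDINATORS


@dataclass
class Sentence:
    """A tokenized sentence of one document."""

    doc_id: str
    sent_index: int
    text: str
    tokens: list[nlp.Token] = field(default_factory=list)


@dataclass
class Segment:
    """One MCSU: a token span of a sentence plus its annotations."""

    segment_id: str
    doc_id: str
    sent_index: int
    token_span: tuple[int, int]
    text: str
    tokens: list[tuple[str, str]] = field(default_factory=list)
    subject_prefix: str | None = None
    subject_tokens: list[tuple[str, str]] = field(default_factory=list)
    split_kind: str = "sentence"  # sentence | clause | phrase
    object_mentions: list = field(default_factory=list)
    feature_mentions: list = field(default_factory=list)

    @property
    def matchable_text(self) -> str:
        """Rendered text including any propagated subject.

        The copied subject is bracketed, as an editorial completion:
        ``[Oral corticosteroids] but increase IL-8.``
        """
        if self.subject_prefix:
            return f"[{self.subject_prefix}] {self.text}"
        return self.text

    @property
    def matchable_tokens(self) -> list[tuple[str, str]]:
        """Subject-prefix tokens followed by the segment's own tokens."""
        return [*self.subject_tokens, *self.tokens]

    @property
    def n_subject_tokens(self) -> int:
        return len(self.subject_tokens)


def split_sentences(text: str, doc_id: str = "") -> list[Sentence]:
    """Split an abstract into ordered, tokenized sentences.

    Abbreviation-aware (``et al.``, ``Fig.``) and robust to decimal
    points; empty text yields an empty list.
    """
    sentences = []
    for index, (start, end) in enumerate(nlp.split_sentence_spans(text)):
        sent_text = text[start:end].rstrip()
        sentences.append(
            Sentence(doc_id, index, sent_text, nlp.tokenize(sent_text))
        )
    return sentences


def pos_tag(sentence: Sentence) -> Sentence:
    """Tag the sentence's tokens with Penn-style POS tags, in place."""
    nlp.tag_tokens(sentence.tokens)
    return sentence


def _has_verb(tokens: list[nlp.Token], start: int, end: int) -> bool:
    return any(nlp.is_verb_tag(tokens[i].tag) for i in range(start, end))


def split_clauses(sentence: Sentence) -> list[tuple[int, int]]:
    """Token spans of the clauses of a POS-tagged sentence.

    Boundaries: a semicolon (kept with the left clause); a subordinating
    conjunction, or a comma followed by a coordinating conjunction, when
    both resulting sides contain a verb.  Without any boundary the whole
    sentence is one span.
    """
    tokens = sentence.tokens
    n = len(tokens)
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    while i < n:
        tok = tokens[i]
        lw = tok.surface.lower()
        if tok.surface == ";" and start < i:
            spans.append((start, i + 1))
            start = i + 1
        elif (
            lw in _CLAUSE_SUBORDINATORS
            and i > start
            and _has_verb(tokens, start, i if tokens[i - 1].surface != "," else i - 1)
            and _has_verb(tokens, i, n)
        ):
            spans.append((start, i))
            start = i
        elif (
            tok.surface == ","
            and i + 1 < n
            and tokens[i + 1].tag == "CC"
            and _has_verb(tokens, start, i)
            and _has_verb(tokens, i + 1, n)
        ):
            spans.append((start, i + 1))
            start = i + 1
        i += 1
    if start < n:
        spans.append((start, n))
    return spans or ([(0, n)] if n else [])


def _feature_positions(
    sentence: Sentence, span: tuple[int, int], lexicon: FeatureLexicon
) -> list[int]:
    return [
        i
        for i in range(span[0], span[1])
        if lexicon.match(sentence.tokens[i].surface, sentence.tokens[i].tag)
        is not None
    ]


def split_phrases_on_features(
    clause: tuple[int, int], sentence: Sentence, lexicon: FeatureLexicon
) -> list[tuple[int, int]]:
    """Cut a clause so that each resulting span holds at most one feature.

    The cut lands immediately before each feature token after the first,
    moved one token left onto a coordinating conjunction when one
    directly precedes the feature (the conjunction joins the right span).
    """
    positions = _feature_positions(sentence, clause, lexicon)
    if len(positions) < 2:
        return [clause]
    cuts = []
    previous = positions[0]
    for pos in positions[1:]:
        # walk left from the feature to a coordinating conjunction, but
        # never across a verb or the previous feature
        cut = pos
        j = pos - 1
        while j > max(clause[0], previous):
            tag = sentence.tokens[j].tag
            if tag == "CC":
                cut = j
                break
            if nlp.is_verb_tag(tag):
                break
            j -= 1
        cuts.append(cut)
        previous = pos
    spans = []
    start = clause[0]
    for cut in cuts:
        if cut > start:
            spans.append((start, cut))
            start = cut
    spans.append((start, clause[1]))
    return spans


def _span_text(sentence: Sentence, span: tuple[int, int]) -> str:
    first = sentence.tokens[span[0]]
    last = sentence.tokens[span[1] - 1]
    return sentence.text[first.start : last.end]


_SKIPPABLE = frozenset(("CC", ",", "RB"))


def _leading_verb(tokens: list[tuple[str, str]]) -> bool:
    for _, tag in tokens:
        if tag in _SKIPPABLE:
            continue
        return nlp.is_verb_tag(tag) or tag == "MD"
    return False


def _subject_of(segment: Segment) -> tuple[str, list[tuple[str, str]]]:
    """Leading noun phrase of a segment: tokens before its first verb."""
    if segment.subject_prefix:
        return segment.subject_prefix, list(segment.subject_tokens)
    collected: list[tuple[str, str]] = []
    for surface, tag in segment.tokens:
        if nlp.is_verb_tag(tag) or tag == "MD":
            break
        if not collected and tag in _SKIPPABLE:
            continue
        collected.append((surface, tag))
    while collected and collected[-1][1] in (",", ".", ";", ":", "SYM", "CC"):
        collected.pop()
    return " ".join(s for s, _ in collected), collected


def propagate_subject(segments: list[Segment], sentence: Sentence) -> list[Segment]:
    """Copy the left sibling's subject into verb-initial phrase splits.

    Only the rendered matchable text changes; token spans are untouched,
    so token coverage of the sentence is preserved.
    """
    for i, segment in enumerate(segments):
        if i == 0 or segment.split_kind != "phrase":
            continue
        if not _leading_verb(segment.tokens):
            continue
        subject, subject_tokens = _subject_of(segments[i - 1])
        if subject:
            segment.subject_prefix = subject
            segment.subject_tokens = subject_tokens
    return segments


def extract_mcsus(sentence: Sentence, lexicon: FeatureLexicon) -> list[Segment]:
    """Run the full extraction cascade on one sentence.

    Tags the sentence if needed, splits clauses, then phrases, renders
    each span, and propagates subjects into verb-initial phrase splits.
    Segments come back in sentence order with ids
    ``{doc}:{sent_index}:{ordinal}``.
    """
    if not sentence.tokens:
        return []
    if any(tok.tag is None for tok in sentence.tokens):
        pos_tag(sentence)
    clauses = split_clauses(sentence)
    segments: list[Segment] = []
    for clause in clauses:
        phrases = split_phrases_on_features(clause, sentence, lexicon)
        for span in phrases:
            kind = "phrase" if len(phrases) > 1 else (
                "clause" if len(clauses) > 1 else "sentence"
            )
            ordinal = len(segments)
            segments.append(
                Segment(
                    segment_id=f"{sentence.doc_id}:{sentence.sent_index}:{ordinal}",
                    doc_id=sentence.doc_id,
                    sent_index=sentence.sent_index,
                    token_span=span,
                    text=_span_text(sentence, span),
                    tokens=[
                        (sentence.tokens[i].surface, sentence.tokens[i].tag or "")
                        for i in range(span[0], span[1])
                    ],
                    split_kind=kind,
                )
            )
    return propagate_subject(segments, sentence)
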