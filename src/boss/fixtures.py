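"""Synthetic corpora with planted ground truth, and golden worked examples.

The generator plants (subject, relation verb, object) triples into
templated abstract sentences — optionally pairing two same-subject
triples into one compound sentence ("A inhibited B but activated C.")
that the segmenter must split — interleaved with object-free distractor
sentences.  Because every planted name comes from the accompanying
dictionary and distractors avoid both dictionary names and relation
triggers, the expected per-object mention and article counts are known
by construction, which lets end-to-end tests check the whole pipeline
exactly without any external data.

Mention-count convention: a compound sentence credits the shared subject
to the first segment only; the second segment carries the subject merely
as propagated matchable text, mirroring how the indexer assigns objects
to segments.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import nlp
from .lexicon import ObjectDictionary, ObjectEntry


@dataclass(frozen=True)
class RelationTemplate:
    """A planted relation with how many times to realize it."""

    subject: str
    lemma: str
    obj: str
    frequency: int = 1


@dataclass
class CorpusSpec:
    """Everything the generator needs; the seed fixes all randomness."""

    n_docs: int
    objects: list[str]
    relation_templates: list[RelationTemplate] = field(default_factory=list)
    distractor_rate: float = 0.0
    year_range: tuple[int, int] = (2000, 2011)
    seed: int = 0

    def __post_init__(self):
        self.relation_templates = [
            t if isinstance(t, RelationTemplate) else RelationTemplate(*t)
            for t in self.relation_templates
        ]
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if not 0.0 <= self.distractor_rate <= 1.0:
            raise ValueError("distractor_rate must be in [0, 1]")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be an inclusive (lo, hi) interval")
        names = set(self.objects)
        for t in self.relation_templates:
            if t.frequency < 1:
                raise ValueError(f"frequency of {t} must be >= 1")
            if t.subject not in names or t.obj not in names:
                raise ValueError(
                    f"template {t} uses a name missing from spec.objects"
                )
            if t.subject == t.obj:
                raise ValueError(f"template {t} relates an object to itself")
        if self.distractor_rate == 1.0 and self.relation_templates:
            raise ValueError(
                "distractor_rate 1.0 leaves no room for relation templates"
            )

    def object_dictionary(self) -> ObjectDictionary:
        """Dictionary of the planted objects (ids OBJ1, OBJ2, ...)."""
        return ObjectDictionary(
            ObjectEntry(f"OBJ{i + 1}", name, object_type="protein", source="spec")
            for i, name in enumerate(self.objects)
        )


@dataclass
class GroundTruth:
    """Counts the generator planted, for exact end-to-end checks."""

    object_mentions: dict[str, int] = field(default_factory=dict)
    object_articles: dict[str, int] = field(default_factory=dict)
    triple_segments: dict[tuple[str, str, str], int] = field(default_factory=dict)


_DISTRACTORS = (
    "The experiments were repeated several times.",
    "These observations were consistent across cohorts.",
    "The methodology followed standard procedures.",
    "Patients were monitored for several months.",
    "No adverse events were recorded during follow-up.",
)


def _past(lemma: str) -> str:
    forms = nlp.verb_inflections(lemma)
    for form, tag in forms.items():
        if tag == "VBD":
            return form
    return lemma


def _third(lemma: str) -> str:
    for form, tag in nlp.verb_inflections(lemma).items():
        if tag == "VBZ":
            return form
    return lemma


def _capitalize(sentence: str) -> str:
    # abstracts capitalize sentence-initial words; lower-case object names
    # still match because dictionary lookup is case-insensitive for them
    return sentence[0].upper() + sentence[1:] if sentence else sentence


def generate_corpus(spec: CorpusSpec) -> tuple[list[dict], GroundTruth]:
    """Realize a corpus spec into abstracts plus its ground truth.

    Returns ``(docs, truth)`` where each doc is ``{"id", "year",
    "text"}``.  Deterministic for a fixed seed.
    """
    rng = random.Random(spec.seed)
    truth = GroundTruth()
    instances: list[RelationTemplate] = []
    for template in spec.relation_templates:
        instances.extend([template] * template.frequency)
    rng.shuffle(instances)

    # pair some consecutive same-subject instances into compound sentences
    units: list[tuple[RelationTemplate, ...]] = []
    i = 0
    while i < len(instances):
        current = instances[i]
        if (
            i + 1 < len(instances)
            and instances[i + 1].subject == current.subject
            and instances[i + 1].lemma != current.lemma
            and rng.random() < 0.5
        ):
            units.append((current, instances[i + 1]))
            i += 2
        else:
            units.append((current,))
            i += 1

    rate = spec.distractor_rate
    if rate >= 1.0:
        n_distractors = 2 * spec.n_docs
    else:
        n_distractors = round(len(units) * rate / (1.0 - rate))
    sentence_plan: list[tuple[RelationTemplate, ...] | None] = list(units)
    sentence_plan.extend([None] * n_distractors)
    rng.shuffle(sentence_plan)

    doc_sentences: list[list[str]] = [[] for _ in range(spec.n_docs)]
    doc_ids = [f"D{i + 1}" for i in range(spec.n_docs)]
    mention_docs: dict[str, set[str]] = {}

    def credit(name: str, doc_id: str) -> None:
        truth.object_mentions[name] = truth.object_mentions.get(name, 0) + 1
        mention_docs.setdefault(name, set()).add(doc_id)

    for position, unit in enumerate(sentence_plan):
        doc_index = position % spec.n_docs
        doc_id = doc_ids[doc_index]
        if unit is None:
            doc_sentences[doc_index].append(rng.choice(_DISTRACTORS))
            continue
        inflect = rng.choice((_past, _third))
        if len(unit) == 1:
            t = unit[0]
            doc_sentences[doc_index].append(
                _capitalize(f"{t.subject} {inflect(t.lemma)} {t.obj}.")
            )
            credit(t.subject, doc_id)
            credit(t.obj, doc_id)
        else:
            first, second = unit
            doc_sentences[doc_index].append(
                _capitalize(
                    f"{first.subject} {inflect(first.lemma)} {first.obj} "
                    f"but {inflect(second.lemma)} {second.obj}."
                )
            )
            # subject is an own-span object of the first segment only
            credit(first.subject, doc_id)
            credit(first.obj, doc_id)
            credit(second.obj, doc_id)
        for t in unit:
            key = (t.subject, t.lemma, t.obj)
            truth.triple_segments[key] = truth.triple_segments.get(key, 0) + 1

    truth.object_articles = {
        name: len(docs) for name, docs in mention_docs.items()
    }
    docs = [
        {
            "id": doc_ids[i],
            "year": rng.randint(*spec.year_range),
            "text": " ".join(doc_sentences[i]),
        }
        for i in range(spec.n_docs)
        if doc_sentences[i]
    ]
    return docs, truth


# --------------------------------------------------------------------------
# Worked-example golden fixtures
# --------------------------------------------------------------------------

EXAMPLE_INHIBITION = "MS-1020 potently inhibited persistently-active STAT3."
EXAMPLE_CONTRADICTION = (
    "Oral corticosteroids decrease CC chemokine but increase IL-8."
)


@dataclass
class PaperFixtures:
    """The two worked sentences, their mini dictionary, and expectations."""

    example1: str
    example2: str
    dictionary: ObjectDictionary
    dictionary_rows: list[tuple[str, str, str, str]]
    expected: dict


def paper_fixtures() -> PaperFixtures:
    """Golden fixture bundle for the worked examples."""
    rows = [
        ("O_MS1020", "MS-1020", "", "drug"),
        ("O_STAT3", "STAT3", "", "protein"),
        ("O_CORT", "oral corticosteroids", "", "drug"),
        ("O_CCCHEM", "CC chemokine", "", "protein"),
        ("O_IL8", "IL-8", "", "protein"),
    ]
    dictionary = ObjectDictionary(
        ObjectEntry(
            object_id=oid,
            canonical_name=name,
            synonyms=[s for s in syns.split("|") if s],
            object_type=otype,
            source="paper_fixtures",
        )
        for oid, name, syns, otype in rows
    )
    expected = {
        "example1_segments": 1,
        "example1_objects": 2,
        "example1_feature_lemma": "inhibit",
        "example2_segments": 2,
        "example2_second_segment_object": "O_IL8",
    }
    return PaperFixtures(
        example1=EXAMPLE_INHIBITION,
        example2=EXAMPLE_CONTRADICTION,
        dictionary=dictionary,
        dictionary_rows=rows,
        expected=expected,
    )
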