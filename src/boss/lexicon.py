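"""Object dictionary and relation-feature lexicon.

The searchable universe of the engine is defined by two curated lists:

* an **object dictionary** of biomedical entities (genes, proteins, drugs,
  diseases) with canonical names and synonyms, matched against segment
  text by dictionary lookup;
* a **feature lexicon** of relation trigger verbs (``inhibit``,
  ``increase``, ...), each carrying one of ten relation types.  The
  bundled default lexicon has 51 lemmas.

Both are plain-text data, loadable from TSV or JSON-lines, so users can
swap in their own compilations without code changes.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from . import nlp
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

OBJECT_TYPES = frozenset({"gene", "protein", "drug", "disease", "other"})

RELATION_TYPES = frozenset({
    "NEGATIVE", "FULL-STOP", "BREAK-DOWN", "DECREASE", "INCREASE",
    "START", "ADDITION", "ASSEMBLY", "UNSPECIFIED", "POSITIVE",
})

FEATURE_ORIGINS = frozenset({"frequency", "ontology"})

# short all-uppercase surfaces (gene symbols like STAT3, WAS) must match
# case-sensitively to avoid clashing with common words
CASE_SENSITIVE_MAX_LEN = 5

_STRIP_CHARS = string.punctuation.replace("-", "") + string.whitespace


def normalize_surface(surface: str) -> str:
    """Case-fold, collapse whitespace and strip edge punctuation.

    Internal hyphens and digits are preserved (``IL-8``, ``MS-1020``).
    Deterministic and idempotent; empty input maps to empty output.
    """
    folded = " ".join(surface.casefold().split())
    stripped = folded.strip(_STRIP_CHARS)
    return " ".join(stripped.split())


def _is_case_sensitive_symbol(surface: str) -> bool:
    s = surface.strip()
    return (
        0 < len(s) <= CASE_SENSITIVE_MAX_LEN
        and s.upper() == s
        and any(c.isalpha() for c in s)
    )


@dataclass
class ObjectEntry:
    """One searchable biomedical object with its surface forms."""

    object_id: str
    canonical_name: str
    synonyms: list[str] = field(default_factory=list)
    object_type: str = "other"
    source: str = ""

    def surface_forms(self) -> list[str]:
        return [self.canonical_name, *self.synonyms]


@dataclass(frozen=True)
class FeatureEntry:
    """One relation trigger verb with its relation type."""

    feature_id: str
    lemma: str
    relation_type: str
    origin: str = "frequency"


@dataclass
class _SurfaceRecord:
    object_id: str
    surface: str
    case_sensitive: bool


class ObjectDictionary:
    """Object entries plus a normalized surface-form index.

    Duplicate surface forms resolve to the first-seen object id (a
    warning is logged), which keeps lookup deterministic and stable
    under reload.
    """

    def __init__(self, entries: Iterable[ObjectEntry] = ()):
        self.entries: list[ObjectEntry] = []
        self.by_id: dict[str, ObjectEntry] = {}
        # normalized surface -> first-seen record
        self.surface_index: dict[str, _SurfaceRecord] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: ObjectEntry) -> None:
        if entry.object_id in self.by_id:
            raise FormatError(f"duplicate object_id {entry.object_id!r}")
        if not entry.canonical_name.strip():
            raise FormatError(f"object {entry.object_id!r} has empty canonical name")
        for surface in entry.surface_forms():
            if not surface.strip():
                raise FormatError(
                    f"object {entry.object_id!r} has an empty surface form"
                )
        if entry.object_type not in OBJECT_TYPES:
            raise FormatError(
                f"object {entry.object_id!r} has unknown type {entry.object_type!r}"
            )
        self.entries.append(entry)
        self.by_id[entry.object_id] = entry
        for surface in entry.surface_forms():
            key = normalize_surface(surface)
            if not key:
                raise FormatError(
                    f"surface {surface!r} of object {entry.object_id!r} "
                    "normalizes to an empty key"
                )
            if key in self.surface_index:
                if self.surface_index[key].object_id != entry.object_id:
                    logger.warning(
                        "surface %r already mapped to %s; keeping first-seen, "
                        "ignoring %s",
                        surface, self.surface_index[key].object_id, entry.object_id,
                    )
                continue
            self.surface_index[key] = _SurfaceRecord(
                entry.object_id, surface, _is_case_sensitive_symbol(surface)
            )

    def lookup(self, surface: str) -> ObjectEntry | None:
        record = self.surface_index.get(normalize_surface(surface))
        if record is None:
            return None
        if record.case_sensitive and surface.strip() != record.surface:
            return None
        return self.by_id[record.object_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ObjectEntry]:
        return iter(self.entries)


class FeatureLexicon:
    """Relation-feature entries with inflection and nominalization maps.

    ``match`` resolves an inflected verb token (``inhibited``) or a
    derivational noun (``inhibitor``, ``inhibition``) to its lexicon
    entry, so queries phrased with nominals still hit the relation.
    """

    def __init__(self, entries: Iterable[FeatureEntry] = ()):
        self.entries: list[FeatureEntry] = []
        self.by_id: dict[str, FeatureEntry] = {}
        self.by_lemma: dict[str, FeatureEntry] = {}
        self._verb_forms: dict[str, FeatureEntry] = {}
        self._nominal_forms: dict[str, FeatureEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: FeatureEntry) -> None:
        if entry.lemma in self.by_lemma:
            raise FormatError(f"duplicate feature lemma {entry.lemma!r}")
        if entry.relation_type not in RELATION_TYPES:
            raise FormatError(
                f"unknown relation_type {entry.relation_type!r} "
                f"for lemma {entry.lemma!r}"
            )
        if entry.origin not in FEATURE_ORIGINS:
            raise FormatError(
                f"unknown origin {entry.origin!r} for lemma {entry.lemma!r}"
            )
        self.entries.append(entry)
        self.by_id[entry.feature_id] = entry
        self.by_lemma[entry.lemma] = entry
        for form in nlp.verb_inflections(entry.lemma):
            self._verb_forms.setdefault(form, entry)
        for form in nlp.derivational_nouns(entry.lemma):
            self._nominal_forms.setdefault(form, entry)

    def match(self, surface: str, tag: str | None) -> FeatureEntry | None:
        """Entry for a verb-tagged lexicon form or a derived nominal."""
        lw = surface.casefold()
        if nlp.is_verb_tag(tag):
            return self._verb_forms.get(lw)
        if tag is not None and tag.startswith("NN"):
            entry = self._nominal_forms.get(lw)
            if entry is not None:
                return entry
        return None

    def match_any_form(self, surface: str) -> FeatureEntry | None:
        """Tag-free form lookup, used on query terms."""
        lw = surface.casefold()
        return self._verb_forms.get(lw) or self._nominal_forms.get(lw)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[FeatureEntry]:
        return iter(self.entries)


def match_feature(token, lexicon: FeatureLexicon) -> FeatureEntry | None:
    """Resolve a POS-tagged token to a feature lexicon entry, if any.

    ``token`` may be an ``nlp.Token`` or a ``(surface, tag)`` pair.
    """
    if isinstance(token, nlp.Token):
        return lexicon.match(token.surface, token.tag)
    surface, tag = token
    return lexicon.match(surface, tag)


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

def _read_lines(path) -> list[str]:
    p = Path(path)
    try:
        text = p.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read {p}: {exc}") from exc
    return text.splitlines()


def load_object_dictionary(path) -> ObjectDictionary:
    """Load an object dictionary from TSV or JSON-lines.

    TSV columns: ``id<TAB>name<TAB>syn1|syn2<TAB>type``; the synonym and
    type columns may be empty.  JSON-lines records carry the same keys
    (``id``, ``name``, ``synonyms``, ``type``).
    """
    dictionary = ObjectDictionary()
    source = str(path)
    for lineno, line in enumerate(_read_lines(path), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.lstrip().startswith("{"):
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{source}:{lineno}: invalid JSON: {exc}") from exc
            object_id = str(rec.get("id", "")).strip()
            name = str(rec.get("name", "")).strip()
            synonyms = [str(s) for s in rec.get("synonyms", []) if str(s).strip()]
            object_type = str(rec.get("type", "other")).strip() or "other"
        else:
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(
                    f"{source}:{lineno}: expected id<TAB>name, got {line!r}"
                )
            object_id = cols[0].strip()
            name = cols[1].strip()
            synonyms = [
                s.strip() for s in (cols[2].split("|") if len(cols) > 2 else [])
                if s.strip()
            ]
            object_type = cols[3].strip() if len(cols) > 3 and cols[3].strip() else "other"
        if not object_id or not name:
            raise FormatError(f"{source}:{lineno}: row lacks id or name")
        dictionary.add(
            ObjectEntry(object_id, name, synonyms, object_type, source=source)
        )
    return dictionary


def bundled_feature_path():
    """Path of the packaged default feature lexicon."""
    return resources.files("boss").joinpath("data/features_table1.tsv")


def load_feature_lexicon(path=None) -> FeatureLexicon:
    """Load the relation-feature lexicon (the bundled file by default).

    TSV columns: ``lemma<TAB>relation_type<TAB>origin``.  The bundled
    default yields 51 entries spanning all 10 relation types.
    """
    if path is None:
        lines = bundled_feature_path().read_text(encoding="utf-8").splitlines()
        source = "features_table1.tsv"
    else:
        lines = _read_lines(path)
        source = str(path)
    lexicon = FeatureLexicon()
    index = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise FormatError(
                f"{source}:{lineno}: expected lemma<TAB>relation_type, got {line!r}"
            )
        index += 1
        lemma = cols[0].strip().casefold()
        relation_type = cols[1].strip()
        origin = cols[2].strip() if len(cols) > 2 and cols[2].strip() else "frequency"
        lexicon.add(FeatureEntry(f"F{index}", lemma, relation_type, origin))
    return lexicon


def save_feature_lexicon(lexicon: FeatureLexicon, path) -> None:
    lines = [f"{e.lemma}\t{e.relation_type}\t{e.origin}" for e in lexicon]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def save_object_dictionary(dictionary: ObjectDictionary, path) -> None:
    lines = [
        "\t".join([e.object_id, e.canonical_name, "|".join(e.synonyms), e.object_type])
        for e in dictionary
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Frequency-based feature derivation
# --------------------------------------------------------------------------

def derive_features_from_corpus(
    corpus: Iterable, k: int | None = None
) -> list[tuple[str, int]]:
    """Rank candidate relation verbs in a corpus by frequency.

    Verb tokens are identified by POS tag, lemmatized and counted over
    every abstract; the top-``k`` lemmas are returned (ties broken
    lexicographically).  ``k=None`` returns the full ranking.  The
    manual screening step that turns candidates into lexicon entries is
    up to the user.
    """
    if k is not None and k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts: dict[str, int] = {}
    for item in corpus:
        text = item.get("text", "") if isinstance(item, dict) else str(item)
        for start, end in nlp.split_sentence_spans(text):
            tokens = nlp.tag_tokens(nlp.tokenize(text[start:end]))
            for tok in tokens:
                if nlp.is_verb_tag(tok.tag):
                    lemma = nlp.lemmatize_verb(tok.surface)
                    counts[lemma] = counts.get(lemma, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if k is None else ranked[:k]
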