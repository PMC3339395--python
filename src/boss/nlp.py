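"""Lightweight rule-based NLP primitives.

Tokenization, sentence boundary detection, Penn-style part-of-speech
tagging and verb lemmatization, tuned for abstracts of biomedical
articles.  The tagger is intentionally small: segmentation and feature
matching downstream only need reliable verb/noun/conjunction decisions
for a known verb vocabulary, not full-coverage tagging.  Biomedical
surface symbols with internal hyphens, digits and slashes (``IL-8``,
``MS-1020``) are kept as single tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# --------------------------------------------------------------------------
# Tokenization
# --------------------------------------------------------------------------

# numbers with decimal/grouping marks, then words (internal -'/+ allowed),
# then any single non-space character
_TOKEN_RE = re.compile(
    r"\d+(?:[.,]\d+)+"
    r"|[A-Za-z0-9](?:[A-Za-z0-9'/+-]*[A-Za-z0-9])?"
    r"|\S"
)


@dataclass
class Token:
    """A surface token with character offsets and an optional POS tag."""

    surface: str
    start: int
    end: int
    tag: str | None = None


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into tokens with half-open character offsets.

    Concatenating token surfaces with the original inter-token gaps
    reproduces the input exactly.
    """
    return [Token(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# --------------------------------------------------------------------------
# Sentence boundary detection
# --------------------------------------------------------------------------

# common abbreviations that take a trailing period without ending a sentence
ABBREVIATIONS = frozenset(
    """al et fig figs eg ie e.g i.e viz vs cf ca approx dr mr mrs ms st no
    nos vol vols ref refs resp spp sp var min max sec etc""".split()
)


def split_sentence_spans(text: str) -> list[tuple[int, int]]:
    """Return half-open character spans of the sentences in ``text``.

    A terminal ``.!?`` ends a sentence when followed by whitespace and an
    upper-case letter, digit or opening quote, unless the preceding word
    is a known abbreviation or a single initial.  Decimal points never
    split because they are not followed by whitespace.
    """
    spans: list[tuple[int, int]] = []
    n = len(text)
    start = 0
    i = 0
    while i < n:
        ch = text[i]
        if ch in ".!?":
            j = i + 1
            while j < n and text[j] in ".!?\"')]":
                j += 1
            if j >= n:
                boundary = True
            elif text[j].isspace():
                k = j
                while k < n and text[k].isspace():
                    k += 1
                boundary = k < n and (
                    text[k].isupper() or text[k].isdigit() or text[k] in "\"'("
                )
            else:
                boundary = False
            if boundary and ch == ".":
                m = re.search(r"([A-Za-z][\w.]*)$", text[:i])
                if m is not None:
                    word = m.group(1).lower().rstrip(".")
                    if word in ABBREVIATIONS:
                        boundary = False
            if boundary:
                spans.append((start, j))
                i = j
                while i < n and text[i].isspace():
                    i += 1
                start = i
                continue
        i += 1
    if start < n and text[start:].strip():
        spans.append((start, n))
    return spans


# --------------------------------------------------------------------------
# Verb vocabulary and inflection tables
# --------------------------------------------------------------------------

# relation verbs common in biomedical abstracts plus general scientific verbs;
# this is tagger vocabulary, independent of any loaded feature lexicon
VERB_LEMMAS = tuple(
    """downregulate inhibit suppress repress interfere inactivate halt block
    limit restrict kill unbind depolymerize disrupt cleave disassemble
    decrease diminish reduce increase enrich initiate activate promote
    acetylate add phosphorylate assemble cross-link attach polymerize bind
    integrate modulate control regulate interact disseminate inherit modify
    stabilize isolate catalyze upregulate stimulate mediate accelerate
    amplify elevate enhance enlarge
    show demonstrate observe report suggest indicate find induce express
    encode cause prevent treat require contain produce affect improve
    perform use study compare measure detect identify reveal confirm play
    remain occur lead result include involve provide describe examine
    investigate determine evaluate assess associate correlate relate
    develop generate target test analyze collect monitor record repeat
    follow need conduct obtain present support propose apply consider
    recruit enroll""".split()
)

_IRREGULAR: dict[str, dict[str, str]] = {
    "bind": {"bound": "VBD", "binds": "VBZ", "binding": "VBG"},
    "find": {"found": "VBD", "finds": "VBZ", "finding": "VBG"},
    "show": {"showed": "VBD", "shown": "VBN", "shows": "VBZ", "showing": "VBG"},
    "lead": {"led": "VBD", "leads": "VBZ", "leading": "VBG"},
}

_VOWELS = "aeiou"


def verb_inflections(lemma: str) -> dict[str, str]:
    """Map each inflected form of a verb ``lemma`` to its Penn tag."""
    forms = {lemma: "VB"}
    if lemma in _IRREGULAR:
        forms.update(_IRREGULAR[lemma])
        return forms
    if lemma.endswith("e"):
        past = lemma + "d"
        gerund = lemma[:-1] + "ing"
    elif lemma.endswith("y") and len(lemma) > 1 and lemma[-2] not in _VOWELS:
        past = lemma[:-1] + "ied"
        gerund = lemma + "ing"
    else:
        past = lemma + "ed"
        gerund = lemma + "ing"
    if lemma.endswith(("s", "x", "z", "ch", "sh")):
        third = lemma + "es"
    elif lemma.endswith("y") and len(lemma) > 1 and lemma[-2] not in _VOWELS:
        third = lemma[:-1] + "ies"
    else:
        third = lemma + "s"
    forms[past] = "VBD"
    forms[gerund] = "VBG"
    forms[third] = "VBZ"
    return forms


def derivational_nouns(lemma: str) -> set[str]:
    """Agent/action noun forms of a verb (inhibit -> inhibitor, inhibition).

    Over-generation is harmless: a produced form only matters if it
    actually occurs as a token.
    """
    stems = [lemma]
    if lemma.endswith("e"):
        stems.append(lemma[:-1])
    out: set[str] = set()
    for stem in stems:
        out.update({stem + "er", stem + "or", stem + "ion"})
    for noun in list(out):
        out.add(noun + "s")
    return out


# form -> (lemma, tag) over the whole tagger verb vocabulary
FORM_TO_LEMMA: dict[str, tuple[str, str]] = {}
for _lemma in VERB_LEMMAS:
    for _form, _tag in verb_inflections(_lemma).items():
        FORM_TO_LEMMA.setdefault(_form, (_lemma, _tag))

_DERIV_NOUN_FORMS: set[str] = set()
for _lemma in VERB_LEMMAS:
    _DERIV_NOUN_FORMS.update(derivational_nouns(_lemma))


# --------------------------------------------------------------------------
# POS tagging
# --------------------------------------------------------------------------

_BE_HAVE_DO = {
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG",
    "does": "VBZ", "do": "VBP", "did": "VBD",
}
_MODALS = frozenset("can could may might must shall should will would".split())
_DETERMINERS = frozenset(
    "a an the this that these those each every some any no both all another".split()
)
_COORD = frozenset(("and", "but", "or", "nor"))
_PREPOSITIONS = frozenset(
    """of in on at by for with to from into over under between among during
    without through against within via upon after before as than per""".split()
)
SUBORDINATORS = frozenset("while whereas although because since if when".split())
_PRONOUNS = frozenset(
    "it its they their we our us he she his her them i you your one".split()
)

_NOMINAL_PREV = frozenset(("DT", "JJ", "CD", "PRP$"))
_NOUNISH_PREV = frozenset(("NN", "NNS", "NNP", "PRP", "RB", "CD"))


def tag_tokens(tokens: list[Token]) -> list[Token]:
    """Assign a Penn-style POS tag to every token, in place.

    Deterministic left-to-right rule cascade: closed-class lists first,
    then the verb-form vocabulary with a determiner-context veto (so
    "a decrease" stays nominal while "corticosteroids decrease" is a
    verb), then suffix heuristics, defaulting to noun.
    """
    prev_tag = "<S>"
    prev_surface = ""
    for index, tok in enumerate(tokens):
        s = tok.surface
        lw = s.lower()
        next_lw = tokens[index + 1].surface.lower() if index + 1 < len(tokens) else ""
        if not any(c.isalnum() for c in s):
            tag = s if s in {",", ".", ";", ":"} else "SYM"
        elif s[0].isdigit():
            tag = "CD"
        elif lw in _BE_HAVE_DO:
            tag = _BE_HAVE_DO[lw]
        elif lw in _MODALS:
            tag = "MD"
        elif lw in _DETERMINERS:
            # upper-case "A" directly before a 3sg verb is a name, not an
            # article ("A inhibits B" vs "A decrease in pressure")
            if s == "A" and FORM_TO_LEMMA.get(next_lw, ("", ""))[1] == "VBZ":
                tag = "NN"
            else:
                tag = "DT"
        elif lw in _COORD:
            tag = "CC"
        elif lw in SUBORDINATORS or lw in _PREPOSITIONS:
            tag = "IN"
        elif lw in _PRONOUNS:
            tag = "PRP"
        elif lw == "not":
            tag = "RB"
        elif lw in FORM_TO_LEMMA:
            _, vtag = FORM_TO_LEMMA[lw]
            if prev_tag in _NOMINAL_PREV:
                tag = "NNS" if vtag == "VBZ" else "NN"
            elif vtag == "VB":
                tag = "VB" if (prev_tag == "MD" or prev_surface == "to") else "VBP"
            else:
                tag = vtag
        elif lw in _DERIV_NOUN_FORMS:
            tag = "NNS" if lw.endswith("s") else "NN"
        elif lw.endswith("ly") and len(lw) > 3:
            tag = "RB"
        elif lw.endswith("ed") and prev_tag in _NOUNISH_PREV:
            tag = "VBD"
        elif lw.endswith("ing") and (prev_tag.startswith("VB") or prev_tag == "RB"):
            tag = "VBG"
        elif lw.endswith("s") and not lw.endswith(("ss", "us", "is")):
            tag = "NNS"
        elif s[0].isupper() and prev_tag != "<S>":
            tag = "NNP"
        else:
            tag = "NN"
        tok.tag = tag
        prev_tag = tag
        prev_surface = lw
    return tokens


def is_verb_tag(tag: str | None) -> bool:
    return tag is not None and tag.startswith("VB")


# --------------------------------------------------------------------------
# Lemmatization
# --------------------------------------------------------------------------

def lemmatize_verb(word: str) -> str:
    """Best-effort base form of a verb token (inhibited -> inhibit)."""
    lw = word.lower()
    if lw in FORM_TO_LEMMA:
        return FORM_TO_LEMMA[lw][0]
    if lw.endswith("ies") and len(lw) > 4:
        return lw[:-3] + "y"
    if lw.endswith("ied") and len(lw) > 4:
        return lw[:-3] + "y"
    for suffix in ("ing", "ed"):
        if lw.endswith(suffix) and len(lw) > len(suffix) + 2:
            stem = lw[: -len(suffix)]
            # undo consonant doubling (stopped -> stop), keep -ll/-ss
            if (
                len(stem) > 2
                and stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and stem[-1] not in "ls"
            ):
                stem = stem[:-1]
            return stem
    if lw.endswith("es") and lw.endswith(("ses", "xes", "zes", "ches", "shes")):
        return lw[:-2]
    if lw.endswith("s") and not lw.endswith("ss") and len(lw) > 3:
        return lw[:-1]
    return lw


# --------------------------------------------------------------------------
# Stopwords
# --------------------------------------------------------------------------

# small closed-class list shared by indexing and query parsing; relation verb
# lemmas never appear here
STOPWORDS = frozenset(
    """a an the this that these those of in on at by for to with and but or
    nor from into as is are was were be been being am it its their they we
    he she not no than then which who whom whose while whereas although
    because since if when such both each very may might can could will
    would shall should must have has had do does did""".split()
)
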