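"""Keyword lexicon and phrase matching for clinical-note annotation.

The lexicon holds the controlled phrase inventory used to score treatment
response from free-text notes of dementia outpatients: drug names for the
two medication classes (SSRIs and cholinesterase inhibitors), cognitive
assessment instrument names, symptom cues split into psychiatric and
cognitive domains, direction cues (improve / no change / worsen), and the
intensity modifiers (markedly / moderately / slightly) that refine a
direction into a seven-point global-impression value.

Direction entries come in two forms:

* plain phrases ("helpful", "no change", "worse") that carry their
  direction on their own, and
* slot templates ("working well" + a medication name, "stable" + a symptom
  cue) that only act as a direction cue when a phrase from their slot set
  co-occurs nearby in the same sentence.

The "stable/controlled" family is deliberately split by slot: paired with a
*psychiatric* symptom cue it signals improvement (stabilising agitation is a
treatment success), while paired with a *cognitive* cue it signals no change
(cognition is expected to decline, so "dementia stable" is neutral).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

__all__ = [
    "LexiconEntry",
    "KeywordLexicon",
    "PhraseMatch",
    "LexiconFormatError",
    "LexiconValidationError",
    "default_lexicon",
    "load_lexicon",
    "dump_lexicon",
    "match_phrases",
    "tokenize",
]

# Slot-set names a template entry may declare.
SLOT_SETS = (
    "drug",               # any SSRI or CEI name
    "psychiatric",        # psychiatric symptom cue
    "cognitive",          # cognitive symptom cue
    "symptom",            # either symptom domain
    "problematic_symptom",  # symptom cue that is not a positive-behavior word
    "positive_behavior",  # hopeful / active / engaging / ...
)

DIRECTION_CATEGORIES = ("improve", "no_change", "worsen")
INTENSITY_CATEGORIES = ("markedly", "moderately", "slightly")

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")


class LexiconFormatError(ValueError):
    """Raised when a lexicon file cannot be parsed."""


class LexiconValidationError(ValueError):
    """Raised when a lexicon violates a structural invariant."""


@dataclass(frozen=True, order=True)
class LexiconEntry:
    """One direction-cue entry: a phrase, optionally tied to a slot set."""

    phrase: str
    slot: Optional[str] = None

    def __post_init__(self) -> None:
        if self.slot is not None and self.slot not in SLOT_SETS:
            raise LexiconValidationError(
                f"unknown slot set {self.slot!r} for phrase {self.phrase!r}"
            )


@dataclass(frozen=True)
class PhraseMatch:
    """A lexicon phrase found in a sentence.

    ``char_span`` is the half-open character interval within the sentence;
    ``token_span`` the half-open token interval (used for proximity rules).
    ``slot`` carries the template's slot-set name for template entries.
    """

    phrase: str
    category: str
    char_span: tuple[int, int]
    token_span: tuple[int, int]
    slot: Optional[str] = None

    @property
    def start(self) -> int:
        return self.char_span[0]

    @property
    def end(self) -> int:
        return self.char_span[1]


# Words of the "more [positive behavior]" improvement template.  These are
# psychiatric descriptors whose *increase* is a good sign, so they are carved
# out of the problematic-symptom slot used by the worsen templates.
POSITIVE_BEHAVIOR_WORDS = frozenset(
    {
        "hopeful",
        "active",
        "engaging",
        "engaged",
        "motivated",
        "interactive",
        "interacting",
        "verbal",
        "communicative",
    }
)

_SECTION_FIELDS = (
    "ssri_names",
    "cei_names",
    "assessment_names",
    "psychiatric_cues",
    "cognitive_cues",
    "improve_cues",
    "no_change_cues",
    "worsen_cues",
    "intensity_markedly",
    "intensity_moderately",
    "intensity_slightly",
)

_ENTRY_FIELDS = frozenset({"improve_cues", "no_change_cues", "worsen_cues"})


@dataclass(frozen=True)
class KeywordLexicon:
    """The controlled phrase inventory, organised by category."""

    ssri_names: frozenset[str]
    cei_names: frozenset[str]
    assessment_names: frozenset[str]
    psychiatric_cues: frozenset[str]
    cognitive_cues: frozenset[str]
    improve_cues: frozenset[LexiconEntry]
    no_change_cues: frozenset[LexiconEntry]
    worsen_cues: frozenset[LexiconEntry]
    intensity_markedly: frozenset[str]
    intensity_moderately: frozenset[str]
    intensity_slightly: frozenset[str]
    positive_behavior: frozenset[str] = field(default=POSITIVE_BEHAVIOR_WORDS)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check structural invariants; raise LexiconValidationError."""
        overlap = {n.casefold() for n in self.ssri_names} & {
            n.casefold() for n in self.cei_names
        }
        if overlap:
            raise LexiconValidationError(
                f"drug name(s) in both SSRI and CEI lists: {sorted(overlap)}"
            )
        # A phrase may not carry two different directions unless the two
        # entries are templates with different slot sets (e.g. the
        # stable-family split between psychiatric and cognitive slots).
        seen: dict[tuple[str, Optional[str]], str] = {}
        for cat, entries in (
            ("improve", self.improve_cues),
            ("no_change", self.no_change_cues),
            ("worsen", self.worsen_cues),
        ):
            for entry in entries:
                key = (entry.phrase.casefold(), entry.slot)
                prev = seen.get(key)
                if prev is not None and prev != cat:
                    raise LexiconValidationError(
                        f"phrase {entry.phrase!r} (slot={entry.slot}) appears in "
                        f"both {prev!r} and {cat!r} direction categories"
                    )
                seen[key] = cat

    def direction_entries(self) -> list[tuple[str, LexiconEntry]]:
        out: list[tuple[str, LexiconEntry]] = []
        for cat, entries in (
            ("improve", self.improve_cues),
            ("no_change", self.no_change_cues),
            ("worsen", self.worsen_cues),
        ):
            out.extend((cat, e) for e in sorted(entries))
        return out

    def all_phrases(self) -> dict[str, set[str]]:
        """Phrase inventory per category (template slots dropped)."""
        out: dict[str, set[str]] = {}
        for f in _SECTION_FIELDS:
            vals = getattr(self, f)
            if f in _ENTRY_FIELDS:
                out[f] = {e.phrase for e in vals}
            else:
                out[f] = set(vals)
        return out


def _entries(*items: str | tuple[str, str]) -> frozenset[LexiconEntry]:
    out = []
    for it in items:
        if isinstance(it, tuple):
            out.append(LexiconEntry(it[0], it[1]))
        else:
            out.append(LexiconEntry(it))
    return frozenset(out)


def default_lexicon() -> KeywordLexicon:
    """The built-in keyword inventory.

    Slashed alternatives of family entries ("repeating him/herself",
    "no major/significant change") are expanded into explicit phrases.
    """
    return KeywordLexicon(
        ssri_names=frozenset(
            {
                "SSRI",
                "SSRIs",
                "citalopram",
                "Celexa",
                "escitalopram",
                "Lexapro",
                "fluoxetine",
                "Prozac",
                "Sarafem",
                "Symbyax",
                "fluvoxamine",
                "Luvox",
                "paroxetine",
                "Paxil",
                "Pexeva",
                "sertraline",
                "Zoloft",
                "vilazodone",
                "Viibryd",
            }
        ),
        cei_names=frozenset(
            {
                "cholinesterase inhibitor",
                "donepezil",
                "Aricept",
                "rivastigmine",
                "Exelon",
                "galantamine",
                "Razadyne",
                "Namzaric",
            }
        ),
        assessment_names=frozenset(
            {
                "MMSE",
                "Mini-Mental State Exam",
                "MoCA",
                "Montreal Cognitive Assessment",
            }
        ),
        psychiatric_cues=frozenset(
            {
                "depression",
                "depressed",
                "anxious",
                "anxiety",
                "mood",
                "ruminating thoughts",
                "nighttime disruption",
                "hallucination",
                "focus",
                "attention",
                "concentration",
                "alert",
                "irritation",
                "irritability",
                "irritated",
                "agitation",
                "agitated",
                "behavior",
                "challenging behavior",
                "panic attack",
                "frustration",
                "apathy",
                "communicative",
                "altered",
                "confusion",
                "mood swings",
                "emotional",
                "emotionally",
                "tearful",
                "crying",
                "anger",
                "positivity",
                "sleep",
                "sad",
                "no energy",
                "personality",
                "paranoia",
                "feeling",
                "impulsivity",
                "active",
                "engaged",
                "engaging",
                "motivated",
                "hopeful",
                "interactive",
                "interacting",
                "verbal",
                "aware",
                "delusions",
                "aggression",
                "dysphoria",
                "elation",
                "euphoria",
                "indifference",
                "disinhibition",
                "disinhibited",
                "labile",
                "lability",
                "motor disturbances",
                "nighttime behavior",
                "psychiatric",
                "psychiatric symptoms",
            }
        ),
        cognitive_cues=frozenset(
            {
                "recall",
                "memory",
                "short-term memory",
                "long-term memory",
                "episodic memory",
                "cognition",
                "cognitive",
                "cognitive performance",
                "cognitive function",
                "cognitive symptoms",
                "dementia",
                "Alzheimer's",
                "word finding difficulty",
                "sharp",
                "sharper",
                "clarity",
                "memory loss",
                "memory lapses",
                "remembering",
                "repeating himself",
                "repeating herself",
                "repeating questions",
                "repetitions",
                "mentation",
            }
        ),
        improve_cues=_entries(
            "improve",
            "improvement",
            "improved",
            "improving",
            "better",
            "well",
            "doing well",
            "help",
            "helped",
            "helpful",
            "benefits",
            "remembering more things",
            "no longer depressed",
            "not depressed",
            "does not feel depressed",
            "sharper",
            "close to normal",
            "almost all the way back to baseline",
            "calmed down",
            "calmer",
            "positive effect",
            "positive turn around",
            ("working well", "drug"),
            ("less", "problematic_symptom"),
            ("decreased", "problematic_symptom"),
            ("improvement in", "problematic_symptom"),
            ("reduction in", "problematic_symptom"),
            ("stable", "psychiatric"),
            ("controlled", "psychiatric"),
            ("under control", "psychiatric"),
            ("now stable", "psychiatric"),
            ("more", "positive_behavior"),
        ),
        no_change_cues=_entries(
            "no change",
            "unchanged",
            "no major change",
            "no significant change",
            "no benefit",
            "uncertain benefit",
            "no improvement",
            "not noticed a difference",
            "not noticed any difference",
            "not made noticeable difference",
            "about the same",
            "around the same",
            "same",
            "not helpful",
            "did not help",
            "didn't help",
            "ineffective",
            "lack of effect",
            "no significant deterioration",
            "no worsening of symptoms",
            "remain",
            "has not done much",
            ("stable", "cognitive"),
            ("stabilized", "cognitive"),
            ("not progressing", "cognitive"),
            ("continued", "symptom"),
            ("still have", "symptom"),
        ),
        worsen_cues=_entries(
            "worsen",
            "worsened",
            "worse",
            "worst",
            "worsening",
            "more trouble",
            "continue to decline",
            "decline in memory",
            "decline in cognition",
            "decline in focus",
            "decline in concentration",
            ("more", "problematic_symptom"),
            ("increased", "problematic_symptom"),
            ("increasingly", "problematic_symptom"),
            ("worsening of", "problematic_symptom"),
            ("advancement in", "problematic_symptom"),
        ),
        intensity_markedly=frozenset(
            {
                "markedly",
                "marked",
                "significant",
                "significantly",
                "much",
                "very",
                "very much",
                "really",
                "great",
                "greatly",
                "quite",
                "dramatic",
                "dramatically",
                "clear",
                "clearly",
                "notable",
                "notably",
                "noticeably",
            }
        ),
        intensity_moderately=frozenset({"moderately", "moderate"}),
        intensity_slightly=frozenset(
            {
                "slightly",
                "slight",
                "minimally",
                "minimal",
                "bit",
                "little",
                "little bit",
                "some",
                "somewhat",
            }
        ),
    )


# ---------------------------------------------------------------------------
# File format: "[section]" headers, one phrase per line, templates written
# "phrase | slot_set".  Blank lines and "#" comments ignored.
# ---------------------------------------------------------------------------

def dump_lexicon(lexicon: KeywordLexicon, path=None) -> str:
    buf = io.StringIO()
    for section in _SECTION_FIELDS:
        buf.write(f"[{section}]\n")
        vals = getattr(lexicon, section)
        if section in _ENTRY_FIELDS:
            for entry in sorted(vals):
                if entry.slot is None:
                    buf.write(f"{entry.phrase}\n")
                else:
                    buf.write(f"{entry.phrase} | {entry.slot}\n")
        else:
            for phrase in sorted(vals):
                buf.write(f"{phrase}\n")
        buf.write("\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _parse_lexicon_text(text: str) -> KeywordLexicon:
    sections: dict[str, list] = {name: [] for name in _SECTION_FIELDS}
    current: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip()
            if name not in sections:
                raise LexiconFormatError(f"line {lineno}: unknown section {name!r}")
            current = name
            continue
        if current is None:
            raise LexiconFormatError(f"line {lineno}: phrase before any section header")
        if current in _ENTRY_FIELDS:
            if "|" in line:
                phrase, _, slot = line.partition("|")
                phrase, slot = phrase.strip(), slot.strip()
                if slot not in SLOT_SETS:
                    raise LexiconFormatError(
                        f"line {lineno}: unknown slot set {slot!r}"
                    )
                sections[current].append(LexiconEntry(phrase, slot))
            else:
                sections[current].append(LexiconEntry(line))
        else:
            sections[current].append(line)
    kwargs = {
        name: frozenset(vals) for name, vals in sections.items()
    }
    return KeywordLexicon(**kwargs)


def load_lexicon(path=None) -> KeywordLexicon:
    """Load a lexicon from ``path``, or the built-in default when absent."""
    if path is None:
        return default_lexicon()
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_lexicon_text(fh.read())


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def tokenize(sentence: str) -> list[tuple[str, int, int]]:
    """Whitespace/punctuation-delimited tokens with character spans."""
    return [
        (m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence)
    ]


def _phrase_tokens(phrase: str) -> tuple[str, ...]:
    return tuple(t[0].casefold() for t in tokenize(phrase))


def _build_index(lexicon: KeywordLexicon):
    """token-tuple -> list of (category, slot, original phrase)."""
    index: dict[tuple[str, ...], list[tuple[str, Optional[str], str]]] = {}

    def add(phrase: str, category: str, slot: Optional[str] = None) -> None:
        toks = _phrase_tokens(phrase)
        if toks:
            index.setdefault(toks, []).append((category, slot, phrase))

    for name in lexicon.ssri_names:
        add(name, "ssri")
    for name in lexicon.cei_names:
        add(name, "cei")
    for name in lexicon.assessment_names:
        add(name, "assessment")
    for cue in lexicon.psychiatric_cues:
        add(cue, "psychiatric")
    for cue in lexicon.cognitive_cues:
        add(cue, "cognitive")
    for cat, entry in lexicon.direction_entries():
        add(entry.phrase, cat, entry.slot)
    for word in lexicon.intensity_markedly:
        add(word, "markedly")
    for word in lexicon.intensity_moderately:
        add(word, "moderately")
    for word in lexicon.intensity_slightly:
        add(word, "slightly")
    return index


def match_phrases(sentence: str, lexicon: KeywordLexicon) -> list[PhraseMatch]:
    """Find lexicon phrases in one sentence.

    Matching is case-insensitive and whole-token.  When two candidate
    matches overlap, only the longer (in characters) survives, so
    "not helpful" suppresses the embedded "helpful"; candidates of equal
    length may share a span (the same word can be both a cognitive cue and
    a direction cue, e.g. "sharper").  Matches return in left-to-right order.
    """
    tokens = tokenize(sentence)
    if not tokens:
        return []
    index = _build_index(lexicon)
    max_len = max(len(k) for k in index)
    folded = [t[0].casefold() for t in tokens]

    candidates: list[PhraseMatch] = []
    for i in range(len(tokens)):
        for L in range(min(max_len, len(tokens) - i), 0, -1):
            key = tuple(folded[i : i + L])
            for category, slot, phrase in index.get(key, ()):
                candidates.append(
                    PhraseMatch(
                        phrase=phrase,
                        category=category,
                        char_span=(tokens[i][1], tokens[i + L - 1][2]),
                        token_span=(i, i + L),
                        slot=slot,
                    )
                )

    # Leftmost-longest suppression: an overlapping candidate loses to a
    # strictly longer accepted span, or to an equal-length earlier span at a
    # different position.  Candidates sharing the exact same span (one word
    # in two categories, e.g. "sharper") are all kept.
    candidates.sort(key=lambda m: (-(m.end - m.start), m.start, m.category))
    accepted: list[PhraseMatch] = []
    for cand in candidates:
        clen = cand.end - cand.start
        shadowed = any(
            a.start < cand.end
            and cand.start < a.end
            and a.char_span != cand.char_span
            and (a.end - a.start) >= clen
            for a in accepted
        )
        if not shadowed:
            accepted.append(cand)
    accepted.sort(key=lambda m: (m.start, m.end, m.category))
    return accepted


def slot_filler_ok(
    filler: PhraseMatch, slot: str, lexicon: KeywordLexicon
) -> bool:
    """Whether ``filler`` can fill a template's slot."""
    cat = filler.category
    phrase = filler.phrase.casefold()
    if slot == "drug":
        return cat in ("ssri", "cei")
    if slot == "psychiatric":
        return cat == "psychiatric"
    if slot == "cognitive":
        return cat == "cognitive"
    if slot == "symptom":
        return cat in ("psychiatric", "cognitive")
    if slot == "problematic_symptom":
        return cat in ("psychiatric", "cognitive") and phrase not in {
            w.casefold() for w in lexicon.positive_behavior
        }
    if slot == "positive_behavior":
        return phrase in {w.casefold() for w in lexicon.positive_behavior}
    return False
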