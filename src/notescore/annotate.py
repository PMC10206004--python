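"""Sentence-level classification of clinical comments.

Each sentence of a note is scanned for lexicon phrases and converted into
zero or more comment annotations: a symptom domain (psychiatric or
cognitive), a direction of change (improve / no change / worsen) and an
optional intensity modifier, together with the evidence spans that fired.
A sentence that mentions a drug and a direction but no symptom cue yields a
single *unclassified* annotation ("sertraline working well"), which the
scorer later routes to the drug class's default domain.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from typing import Optional

from .lexicon import KeywordLexicon, PhraseMatch, match_phrases, slot_filler_ok

__all__ = [
    "AUTHOR_ROLES",
    "ClinicalNote",
    "CommentAnnotation",
    "segment_sentences",
    "classify_comment",
    "annotate_note",
    "annotate_notes",
]

AUTHOR_ROLES = ("clinician", "caregiver", "patient", "unknown")

# Author priority used by the scorer: lower rank wins.  "unknown" is ranked
# below patient (conservative: unattributed text carries the least weight).
AUTHOR_PRIORITY = {role: i for i, role in enumerate(AUTHOR_ROLES)}

DOMAINS = ("psychiatric", "cognitive", "unclassified")
DIRECTIONS = ("improve", "no_change", "worsen", "none")
INTENSITIES = ("markedly", "moderately", "slightly", "none")

# Proximity windows, in intervening-token counts (0 = adjacent).
SLOT_WINDOW = 8     # template direction cue <-> slot filler
INTENSITY_WINDOW = 3  # intensity modifier <-> direction cue

_SENTENCE_RE = re.compile(r"[^.!?\n]+[.!?]?")


@dataclass(frozen=True)
class ClinicalNote:
    note_id: str
    patient_id: str
    date: dt.date
    author_role: str
    text: str

    def __post_init__(self) -> None:
        if self.author_role not in AUTHOR_ROLES:
            raise ValueError(f"author_role {self.author_role!r} not in {AUTHOR_ROLES}")
        if not isinstance(self.date, dt.date):
            raise TypeError("date must be a datetime.date")


@dataclass(frozen=True)
class CommentAnnotation:
    """One classified clinical comment."""

    note_id: str
    patient_id: str
    date: dt.date
    author_role: str
    drug_classes_mentioned: frozenset[str]
    domain: str
    direction: str
    intensity: str = "none"
    evidence: tuple[PhraseMatch, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"bad domain {self.domain!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"bad direction {self.direction!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"bad intensity {self.intensity!r}")
        if self.direction == "none" and self.intensity != "none":
            raise ValueError("direction=none requires intensity=none")


def segment_sentences(text: str) -> list[tuple[str, int, int]]:
    """Split text into (sentence, start, end) spans.

    Splits on sentence-final punctuation and newlines; an unterminated tail
    is its own sentence.  Spans cover all non-empty stretches of the text.
    """
    out = []
    for m in _SENTENCE_RE.finditer(text):
        s = m.group(0)
        stripped = s.strip()
        if stripped:
            lead = len(s) - len(s.lstrip())
            out.append((stripped, m.start() + lead, m.start() + lead + len(stripped)))
    return out


def _token_distance(a: PhraseMatch, b: PhraseMatch) -> int:
    """Intervening tokens between two matches (0 when adjacent/overlapping)."""
    if a.token_span[0] > b.token_span[0]:
        a, b = b, a
    return max(0, b.token_span[0] - a.token_span[1])


def _resolve_direction_candidates(
    matches: list[PhraseMatch], lexicon: KeywordLexicon
) -> list[tuple[PhraseMatch, Optional[PhraseMatch]]]:
    """Active direction cues: (cue match, slot filler or None).

    Plain entries are always active; template entries activate only when a
    slot-filling match sits within SLOT_WINDOW tokens, and bind the nearest
    such filler.
    """
    active = []
    for m in matches:
        if m.category not in ("improve", "no_change", "worsen"):
            continue
        if m.slot is None:
            active.append((m, None))
            continue
        fillers = [
            f
            for f in matches
            if f is not m
            and slot_filler_ok(f, m.slot, lexicon)
            and _token_distance(m, f) < SLOT_WINDOW
        ]
        if fillers:
            filler = min(fillers, key=lambda f: (_token_distance(m, f), f.start))
            active.append((m, filler))
    return active


def _nearest_intensity(
    cue: PhraseMatch, matches: list[PhraseMatch]
) -> str:
    mods = [
        m
        for m in matches
        if m.category in ("markedly", "moderately", "slightly")
        and _token_distance(cue, m) < INTENSITY_WINDOW
    ]
    if not mods:
        return "none"
    best = min(mods, key=lambda m: (_token_distance(cue, m), m.start))
    return best.category


_DIRECTION_RANK = {"improve": 0, "worsen": 1, "no_change": 2}


def _pick_direction(
    candidates: list[tuple[PhraseMatch, Optional[PhraseMatch]]],
    anchor: Optional[PhraseMatch],
) -> Optional[tuple[PhraseMatch, Optional[PhraseMatch]]]:
    """Choose one direction cue for a fragment.

    Improve and worsen each beat no-change within a sentence ("slightly
    worse or around the same" reads as worse).  Among the surviving cues
    the one nearest the anchor (the domain's symptom cue, or the drug
    mention for unclassified fragments) wins, so a two-domain sentence
    pairs each domain with its own direction; remaining ties go to improve
    over worsen, then leftmost.
    """
    if not candidates:
        return None
    pool = list(candidates)
    if any(c[0].category in ("improve", "worsen") for c in pool):
        pool = [c for c in pool if c[0].category != "no_change"]
    if anchor is not None:
        pool.sort(
            key=lambda c: (
                _token_distance(c[0], anchor),
                _DIRECTION_RANK[c[0].category],
                c[0].start,
            )
        )
    else:
        pool.sort(key=lambda c: (_DIRECTION_RANK[c[0].category], c[0].start))
    return pool[0]


def classify_comment(
    sentence: str, lexicon: KeywordLexicon
) -> list[dict]:
    """Classify one sentence into annotation fragments.

    Returns a list of dicts with keys domain, direction, intensity,
    evidence, drug_classes — one per symptom domain with a direction match,
    or a single unclassified fragment when only a drug mention anchors the
    direction.  Empty when nothing scorable is present.
    """
    matches = match_phrases(sentence, lexicon)
    if not matches:
        return []

    drug_matches = [m for m in matches if m.category in ("ssri", "cei")]
    drug_classes = frozenset(
        {"SSRI" if m.category == "ssri" else "CEI" for m in drug_matches}
    )
    candidates = _resolve_direction_candidates(matches, lexicon)

    fragments: list[dict] = []
    for domain, cue_cat in (("psychiatric", "psychiatric"), ("cognitive", "cognitive")):
        symptom_cues = [m for m in matches if m.category == cue_cat]
        if not symptom_cues:
            continue
        # Templates with a domain-specific slot belong to the domain that
        # fills them: "anxiety stable" must not drive a cognitive fragment.
        usable = [
            (cue, filler)
            for cue, filler in candidates
            if cue.slot not in ("psychiatric", "cognitive")
            or (filler is not None and filler.category == cue_cat)
        ]
        anchor = symptom_cues[0]
        if len(symptom_cues) > 1 and usable:
            # anchor on the symptom cue closest to any usable direction cue
            anchor = min(
                symptom_cues,
                key=lambda s: min(_token_distance(s, c[0]) for c in usable),
            )
        chosen = _pick_direction(usable, anchor)
        if chosen is None:
            continue
        cue, filler = chosen
        evidence = [anchor, cue] + ([filler] if filler is not None else [])
        fragments.append(
            {
                "domain": domain,
                "direction": cue.category,
                "intensity": _nearest_intensity(cue, matches),
                "evidence": tuple(dict.fromkeys(evidence)),
                "drug_classes": drug_classes,
            }
        )

    if not fragments and drug_matches:
        # drug mention + direction, no symptom cue -> unclassified
        chosen = _pick_direction(candidates, drug_matches[0])
        if chosen is not None:
            cue, filler = chosen
            evidence = [drug_matches[0], cue] + (
                [filler] if filler is not None else []
            )
            fragments.append(
                {
                    "domain": "unclassified",
                    "direction": cue.category,
                    "intensity": _nearest_intensity(cue, matches),
                    "evidence": tuple(dict.fromkeys(evidence)),
                    "drug_classes": drug_classes,
                }
            )
    return fragments


def annotate_note(
    note: ClinicalNote, lexicon: KeywordLexicon
) -> list[CommentAnnotation]:
    """Annotate every sentence of a note.

    Yields one annotation per (sentence, domain) with a direction match,
    plus unclassified annotations for drug-anchored comments.  Sentences
    with no lexicon evidence contribute nothing.
    """
    annotations = []
    for sentence, _start, _end in segment_sentences(note.text):
        for frag in classify_comment(sentence, lexicon):
            annotations.append(
                CommentAnnotation(
                    note_id=note.note_id,
                    patient_id=note.patient_id,
                    date=note.date,
                    author_role=note.author_role,
                    drug_classes_mentioned=frag["drug_classes"],
                    domain=frag["domain"],
                    direction=frag["direction"],
                    intensity=frag["intensity"],
                    evidence=frag["evidence"],
                )
            )
    return annotations


def annotate_notes(
    notes: list[ClinicalNote], lexicon: KeywordLexicon
) -> list[CommentAnnotation]:
    out: list[CommentAnnotation] = []
    for note in notes:
        out.extend(annotate_note(note, lexicon))
    return out
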