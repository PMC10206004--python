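"""NOTE and CIBIC-plus score assignment, responder classification, and
MMSE-change computation.

Per medication episode and symptom domain, the scorer selects one
prioritized comment from the episode's annotations and maps it to

* NOTE, a three-point Likert value (1 improved, 2 no change, 3 worse) with
  side codes 0 = N/A (nothing scorable) and 0.5 = intolerant (drug stopped
  for an adverse event / allergy-listed), and
* CIBIC-plus, the seven-point global change value (1 markedly improved ...
  4 unchanged ... 7 markedly worse), which additionally needs an intensity
  modifier for improve/worsen comments; comments that carry a direction but
  no gradable modifier ("donepezil working well") are CIBIC-plus N/A.

Evidence prioritization: improvement marks the drug effective even when a
later decline is documented, so improve beats worsen beats no change across
the whole episode; within the winning direction, clinician comments beat
caregiver comments beat patient comments; for the cognitive domain,
comments dated at an observed MMSE change win; remaining ties resolve to
the comment closest to six months (182 days) after the episode start,
earlier date first.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotate import AUTHOR_PRIORITY, CommentAnnotation
from .episodes import MedicationEpisode, WASHOUT_DAYS

__all__ = [
    "NOTE_NA",
    "NOTE_INTOLERANT",
    "TARGET_DAYS",
    "MMSE_WINDOW_DAYS",
    "EpisodeScore",
    "CognitiveScoreRecord",
    "ResponderClassification",
    "default_domain",
    "select_prioritized_comment",
    "assign_note",
    "assign_cibic",
    "score_episode",
    "classify_responder",
    "convert_moca_to_mmse",
    "compute_mmse_change",
    "collapse_cibic",
]

NOTE_NA = 0.0
NOTE_INTOLERANT = 0.5
TARGET_DAYS = 182        # "closest to 6 months"
MMSE_WINDOW_DAYS = 14    # "within 2 weeks", inclusive

_DIRECTION_TO_NOTE = {"improve": 1.0, "no_change": 2.0, "worsen": 3.0}
_IMPROVE_CIBIC = {"markedly": 1, "moderately": 2, "slightly": 3}
_WORSEN_CIBIC = {"slightly": 5, "moderately": 6, "markedly": 7}
_DIRECTION_RANK = {"improve": 0, "worsen": 1, "no_change": 2}


@dataclass(frozen=True)
class EpisodeScore:
    episode_id: str
    domain: str  # "psychiatric" | "cognitive"
    note_value: float       # 0, 0.5, 1, 2, 3
    cibic_value: float      # 0, 0.5, 1..7
    evidence_date: Optional[dt.date] = None
    evidence_annotation: Optional[CommentAnnotation] = None

    def __post_init__(self) -> None:
        if self.note_value not in (0.0, 0.5, 1.0, 2.0, 3.0):
            raise ValueError(f"bad NOTE value {self.note_value}")
        if self.cibic_value not in (0.0, 0.5, 1, 2, 3, 4, 5, 6, 7):
            raise ValueError(f"bad CIBIC-plus value {self.cibic_value}")
        ok = {
            0.5: {0.5},
            1.0: {0, 1, 2, 3},
            2.0: {0, 4},
            3.0: {0, 5, 6, 7},
            0.0: {0},
        }[self.note_value]
        if self.cibic_value not in ok:
            raise ValueError(
                f"inconsistent scales: NOTE {self.note_value}, "
                f"CIBIC-plus {self.cibic_value}"
            )


@dataclass(frozen=True)
class CognitiveScoreRecord:
    patient_id: str
    date: dt.date
    instrument: str  # "MMSE" | "MoCA"
    raw_score: int

    def __post_init__(self) -> None:
        if self.instrument not in ("MMSE", "MoCA"):
            raise ValueError(f"bad instrument {self.instrument!r}")
        if not 0 <= self.raw_score <= 30:
            raise ValueError(f"raw score {self.raw_score} out of 0-30")

    @property
    def mmse_equivalent(self) -> int:
        if self.instrument == "MMSE":
            return self.raw_score
        return convert_moca_to_mmse(self.raw_score)


@dataclass(frozen=True)
class ResponderClassification:
    episode_id: str
    drug_class: str
    category: str  # responder | non_responder | intolerant | not_evaluable

    def __post_init__(self) -> None:
        if self.category not in (
            "responder",
            "non_responder",
            "intolerant",
            "not_evaluable",
        ):
            raise ValueError(f"bad category {self.category!r}")


def default_domain(drug_class: str) -> str:
    """The prioritized symptom domain for a drug class."""
    return "psychiatric" if drug_class == "SSRI" else "cognitive"


def _author_rank(role: str) -> int:
    return AUTHOR_PRIORITY.get(role, len(AUTHOR_PRIORITY))


def select_prioritized_comment(
    annotations: Sequence[CommentAnnotation],
    episode: MedicationEpisode,
    domain: str,
    mmse_change_dates: Sequence[dt.date] = (),
    target_days: int = TARGET_DAYS,
    washout_days: int = WASHOUT_DAYS,
) -> Optional[CommentAnnotation]:
    """Pick the single comment that scores this episode and domain.

    ``annotations`` is the candidate pool for this domain (see
    ``assign_note`` for how unclassified comments are routed).  Returns
    None when nothing falls inside the episode window.
    """
    pool = [a for a in annotations if episode.covers(a.date, washout_days)]
    if not pool:
        return None

    best_rank = min(_DIRECTION_RANK[a.direction] for a in pool)
    pool = [a for a in pool if _DIRECTION_RANK[a.direction] == best_rank]

    best_author = min(_author_rank(a.author_role) for a in pool)
    pool = [a for a in pool if _author_rank(a.author_role) == best_author]

    if domain == "cognitive" and mmse_change_dates:
        matched = [
            a
            for a in pool
            if any(
                abs((a.date - d).days) <= MMSE_WINDOW_DAYS
                for d in mmse_change_dates
            )
        ]
        if matched:
            pool = matched

    def key(a: CommentAnnotation):
        offset = (a.date - episode.start_date).days
        return (abs(offset - target_days), a.date)

    return min(pool, key=key)


def _candidate_pool(
    episode: MedicationEpisode,
    annotations: Sequence[CommentAnnotation],
    domain: str,
) -> list[CommentAnnotation]:
    """Domain-matched annotations, plus unclassified drug comments when
    ``domain`` is the drug class's default domain."""
    pool = [a for a in annotations if a.domain == domain]
    if domain == default_domain(episode.drug_class):
        pool.extend(
            a
            for a in annotations
            if a.domain == "unclassified"
            and episode.drug_class in a.drug_classes_mentioned
        )
    return pool


def assign_note(
    episode: MedicationEpisode,
    annotations: Sequence[CommentAnnotation],
    domain: str,
    mmse_change_dates: Sequence[dt.date] = (),
    target_days: int = TARGET_DAYS,
) -> EpisodeScore:
    """Assign the NOTE (and jointly the CIBIC-plus) value for one domain."""
    if episode.intolerant:
        return EpisodeScore(episode.episode_id, domain, NOTE_INTOLERANT, 0.5)
    pool = _candidate_pool(episode, annotations, domain)
    chosen = select_prioritized_comment(
        pool, episode, domain, mmse_change_dates, target_days
    )
    if chosen is None:
        return EpisodeScore(episode.episode_id, domain, NOTE_NA, 0.0)
    note = _DIRECTION_TO_NOTE[chosen.direction]
    cibic = _cibic_from(chosen)
    return EpisodeScore(
        episode.episode_id,
        domain,
        note,
        cibic,
        evidence_date=chosen.date,
        evidence_annotation=chosen,
    )


def _cibic_from(annotation: CommentAnnotation) -> float:
    if annotation.direction == "no_change":
        return 4
    table = (
        _IMPROVE_CIBIC if annotation.direction == "improve" else _WORSEN_CIBIC
    )
    return table.get(annotation.intensity, 0.0)


def assign_cibic(
    episode: MedicationEpisode,
    annotations: Sequence[CommentAnnotation],
    domain: str,
    mmse_change_dates: Sequence[dt.date] = (),
    target_days: int = TARGET_DAYS,
) -> EpisodeScore:
    """CIBIC-plus assignment; shares its evidence with ``assign_note``."""
    return assign_note(episode, annotations, domain, mmse_change_dates, target_days)


def score_episode(
    episode: MedicationEpisode,
    annotations: Sequence[CommentAnnotation],
    mmse_change_dates: Sequence[dt.date] = (),
    target_days: int = TARGET_DAYS,
) -> dict[str, EpisodeScore]:
    """Score both domains of one episode."""
    return {
        domain: assign_note(
            episode, annotations, domain, mmse_change_dates, target_days
        )
        for domain in ("psychiatric", "cognitive")
    }


def classify_responder(
    score: EpisodeScore, drug_class: str
) -> ResponderClassification:
    """Responder status from the drug class's prioritized-domain score.

    SSRI responders improved psychiatrically; no change or worse is
    non-response.  CEI responders improved *or held stable* cognitively
    (continued decline is the expected course); worse is non-response.
    """
    if score.domain != default_domain(drug_class):
        raise ValueError(
            f"{drug_class} responder classification needs the "
            f"{default_domain(drug_class)} score, got {score.domain}"
        )
    v = score.note_value
    if v == NOTE_INTOLERANT:
        category = "intolerant"
    elif v == NOTE_NA:
        category = "not_evaluable"
    elif drug_class == "SSRI":
        category = "responder" if v == 1.0 else "non_responder"
    else:
        category = "responder" if v in (1.0, 2.0) else "non_responder"
    return ResponderClassification(score.episode_id, drug_class, category)


# ---------------------------------------------------------------------------
# MoCA -> MMSE conversion and MMSE change
# ---------------------------------------------------------------------------

# Synthetic MoCA->MMSE crosswalk (index = MoCA 0..30).  A constructed
# monotone stand-in for published equipercentile-equating tables, which are
# not redistributable here; it preserves their qualitative shape (MoCA
# scores run lower than MMSE over most of the range, both ceilings map to
# ceiling).  Replaceable by any published table of the same shape.
_SYNTHETIC_MOCA_TO_MMSE = (
    0, 2, 4, 5, 7, 8, 10, 11, 12, 13, 15,
    16, 17, 18, 19, 20, 21, 22, 22, 23, 24,
    25, 25, 26, 27, 27, 28, 28, 29, 29, 30,
)


def convert_moca_to_mmse(raw: int) -> int:
    """MMSE equivalent of a raw MoCA score via the bundled crosswalk."""
    if not 0 <= raw <= 30:
        raise ValueError(f"MoCA score {raw} out of 0-30")
    return _SYNTHETIC_MOCA_TO_MMSE[raw]


def _nearest_record(
    records: Sequence[CognitiveScoreRecord],
    target: dt.date,
    window_days: int,
) -> Optional[CognitiveScoreRecord]:
    eligible = [
        r for r in records if abs((r.date - target).days) <= window_days
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda r: (abs((r.date - target).days), r.date))


def compute_mmse_change(
    records: Sequence[CognitiveScoreRecord],
    episode: MedicationEpisode,
    comment_date: dt.date,
    window_days: int = MMSE_WINDOW_DAYS,
) -> Optional[int]:
    """Post-minus-pre MMSE change for one episode and comment date.

    Pre is the record nearest the episode start within the window; post is
    the record nearest the comment date within the window.  None when
    either is missing.  MoCA records enter through their MMSE equivalent.
    """
    recs = [r for r in records if r.patient_id == episode.patient_id]
    pre = _nearest_record(recs, episode.start_date, window_days)
    post = _nearest_record(recs, comment_date, window_days)
    if pre is None or post is None:
        return None
    return post.mmse_equivalent - pre.mmse_equivalent


def collapse_cibic(cibic_value: float) -> float:
    """Collapse a 7-point CIBIC-plus value onto the 3-point NOTE scale."""
    if cibic_value in (0.0, 0.5):
        return cibic_value
    if cibic_value in (1, 2, 3):
        return 1.0
    if cibic_value == 4:
        return 2.0
    return 3.0
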