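"""End-to-end orchestration: notes + prescriptions -> scored episodes.

Ties the stages together: annotate every note, build medication episodes
from the prescription records, screen them with the exclusion rules, select
and score the prioritized evidence per included episode and domain, and
classify responders on each drug class's prioritized domain (psychiatric
for SSRIs, cognitive for CEIs).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .annotate import ClinicalNote, CommentAnnotation, annotate_notes
from .episodes import (
    MedicationEpisode,
    PrescriptionRecord,
    WASHOUT_DAYS,
    apply_exclusions,
    build_episodes,
)
from .lexicon import KeywordLexicon, default_lexicon
from .scoring import (
    CognitiveScoreRecord,
    EpisodeScore,
    ResponderClassification,
    TARGET_DAYS,
    classify_responder,
    compute_mmse_change,
    default_domain,
    score_episode,
)

__all__ = ["PipelineResult", "score_corpus"]


@dataclass
class PipelineResult:
    annotations: list[CommentAnnotation]
    episodes: list[MedicationEpisode]
    scores: list[EpisodeScore]
    classifications: list[ResponderClassification]
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def included_episodes(self) -> list[MedicationEpisode]:
        return [e for e in self.episodes if e.status == "included"]

    def scores_frame(self) -> pd.DataFrame:
        """One row per included episode x domain."""
        episodes = {e.episode_id: e for e in self.episodes}
        responder = {c.episode_id: c.category for c in self.classifications}
        rows = []
        for s in self.scores:
            ep = episodes[s.episode_id]
            prioritized = s.domain == default_domain(ep.drug_class)
            rows.append(
                {
                    "episode_id": s.episode_id,
                    "patient_id": ep.patient_id,
                    "drug_class": ep.drug_class,
                    "domain": s.domain,
                    "prioritized": prioritized,
                    "note_value": s.note_value,
                    "cibic_value": s.cibic_value,
                    "evidence_date": s.evidence_date,
                    "responder": responder.get(s.episode_id) if prioritized else None,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "episode_id",
                "patient_id",
                "drug_class",
                "domain",
                "prioritized",
                "note_value",
                "cibic_value",
                "evidence_date",
                "responder",
            ],
        )


def score_corpus(
    notes: Sequence[ClinicalNote],
    prescriptions: Sequence[PrescriptionRecord],
    cognitive: Sequence[CognitiveScoreRecord] = (),
    lexicon: Optional[KeywordLexicon] = None,
    washout_days: int = WASHOUT_DAYS,
    target_days: int = TARGET_DAYS,
) -> PipelineResult:
    """Run the full annotate -> episode -> score -> classify pipeline."""
    lexicon = lexicon or default_lexicon()
    annotations = annotate_notes(list(notes), lexicon)

    ann_by_patient: dict[str, list[CommentAnnotation]] = {}
    for a in annotations:
        ann_by_patient.setdefault(a.patient_id, []).append(a)
    note_dates: dict[str, list[dt.date]] = {}
    for n in notes:
        note_dates.setdefault(n.patient_id, []).append(n.date)
    cog_by_patient: dict[str, list[CognitiveScoreRecord]] = {}
    for r in cognitive:
        cog_by_patient.setdefault(r.patient_id, []).append(r)

    episodes = build_episodes(prescriptions, washout_days, lexicon)
    episodes = [
        apply_exclusions(e, note_dates.get(e.patient_id, ()), washout_days)
        for e in episodes
    ]

    scores: list[EpisodeScore] = []
    classifications: list[ResponderClassification] = []
    for ep in episodes:
        if ep.status != "included":
            continue
        patient_ann = ann_by_patient.get(ep.patient_id, [])
        mmse_dates = [
            r.date
            for r in cog_by_patient.get(ep.patient_id, [])
            if r.date > ep.start_date
        ]
        domain_scores = score_episode(ep, patient_ann, mmse_dates, target_days)
        scores.extend(domain_scores.values())
        classifications.append(
            classify_responder(
                domain_scores[default_domain(ep.drug_class)], ep.drug_class
            )
        )

    result = PipelineResult(
        annotations=annotations,
        episodes=episodes,
        scores=scores,
        classifications=classifications,
    )
    result.stage_counts = {
        "notes": len(notes),
        "annotations": len(annotations),
        "episodes_screened": len(episodes),
        "episodes_excluded": sum(e.status == "excluded" for e in episodes),
        "episodes_included": len(result.included_episodes),
    }
    return result


def mmse_changes(
    result: PipelineResult,
    cognitive: Sequence[CognitiveScoreRecord],
) -> pd.DataFrame:
    """Pre-to-post cognitive change per included episode (cognitive domain).

    Uses each episode's cognitive-domain evidence date as the comment date;
    episodes without a dated cognitive comment or without in-window screens
    drop out.
    """
    episodes = {e.episode_id: e for e in result.episodes}
    rows = []
    for s in result.scores:
        if s.domain != "cognitive" or s.evidence_date is None:
            continue
        ep = episodes[s.episode_id]
        delta = compute_mmse_change(list(cognitive), ep, s.evidence_date)
        if delta is not None:
            rows.append(
                {
                    "episode_id": s.episode_id,
                    "drug_class": ep.drug_class,
                    "note_value": s.note_value,
                    "mmse_change": delta,
                }
            )
    return pd.DataFrame(
        rows, columns=["episode_id", "drug_class", "note_value", "mmse_change"]
    )
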