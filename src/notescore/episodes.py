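"""Medication-episode construction and exclusion rules.

A patient's prescription records for one drug class are merged into
*episodes* of continuous use.  Consecutive usage periods (a switch to
another drug of the same class, or a documented gap in use) merge into one
episode when separated by less than the washout window (90 days by
default); a gap or switch of at least the washout starts a new episode.
Each included episode is an independent observation unit downstream.

Episodes are then screened with the study's exclusion rules: start date too
far from the index (first-order) date, recent SNRI use before an SSRI,
unknown start, protected records, never-started or diagnosis-change
discontinuations, and absence of any follow-up documentation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .lexicon import KeywordLexicon, default_lexicon

__all__ = [
    "PrescriptionRecord",
    "MedicationEpisode",
    "EpisodeValidationError",
    "WASHOUT_DAYS",
    "EARLY_START_DAYS",
    "LATE_START_DAYS",
    "EXCLUSION_REASONS",
    "drug_class_of",
    "build_episodes",
    "apply_exclusions",
]

# "3 months" == 90 days; "6 months" == 182 days; "after 3 months from the
# index date" == 91 days.  All windows closed at both ends.
WASHOUT_DAYS = 90
EARLY_START_DAYS = 182
LATE_START_DAYS = 91

KNOWN_FLAGS = frozenset(
    {
        "never_started",
        "start_unknown",
        "record_protected",
        "discontinued_diagnosis_change",
        "discontinued_adverse_event",
        "allergy_listed",
    }
)

EXCLUSION_REASONS = (
    "early_start",
    "late_start",
    "snri_carryover",
    "start_unknown",
    "record_protected",
    "no_followup",
    "never_started",
    "diagnosis_change",
)

# CEIs prescribed for non-dementia indications, filtered at ingestion.
NON_DEMENTIA_CEIS = frozenset({"neostigmine", "bloxiverz", "pyridostigmine", "mestinon"})


class EpisodeValidationError(ValueError):
    """Raised for inconsistent overlapping prescription records."""


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    drug_name: str
    order_date: dt.date
    reported_start_date: Optional[dt.date] = None
    reported_stop_date: Optional[dt.date] = None
    flags: frozenset[str] = frozenset()
    prior_snri_end_date: Optional[dt.date] = None
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.flags) - KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")
        if (
            self.reported_start_date is not None
            and self.reported_stop_date is not None
            and self.reported_stop_date < self.reported_start_date
        ):
            raise EpisodeValidationError(
                f"record {self.record_id or self.drug_name}: stop before start"
            )

    @property
    def start(self) -> dt.date:
        """Best available start: reported start if present, else order date."""
        return self.reported_start_date or self.order_date


@dataclass(frozen=True)
class MedicationEpisode:
    episode_id: str
    patient_id: str
    drug_class: str  # "SSRI" | "CEI"
    drug_sequence: tuple[str, ...]
    start_date: dt.date
    end_date: Optional[dt.date]
    index_date: dt.date
    status: str = "included"
    exclusion_reason: Optional[str] = None
    intolerant: bool = False
    flags: frozenset[str] = frozenset()
    prior_snri_end_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.drug_class not in ("SSRI", "CEI"):
            raise ValueError(f"bad drug_class {self.drug_class!r}")
        if (self.status == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("status=excluded iff exclusion_reason present")

    def covers(self, date: dt.date, washout_days: int = WASHOUT_DAYS) -> bool:
        """Whether a comment on ``date`` can speak to this episode.

        Open-ended episodes accept any date at or after start; ended
        episodes accept dates up to end + washout (carryover window).
        """
        if date < self.start_date:
            return False
        if self.end_date is None:
            return True
        return date <= self.end_date + dt.timedelta(days=washout_days)


def drug_class_of(drug_name: str, lexicon: Optional[KeywordLexicon] = None) -> Optional[str]:
    """Map a drug name to "SSRI"/"CEI", or None for out-of-scope drugs."""
    lexicon = lexicon or default_lexicon()
    name = drug_name.casefold()
    if name in NON_DEMENTIA_CEIS:
        return None
    if name in {n.casefold() for n in lexicon.ssri_names}:
        return "SSRI"
    if name in {n.casefold() for n in lexicon.cei_names}:
        return "CEI"
    return None


def build_episodes(
    records: Sequence[PrescriptionRecord],
    washout_days: int = WASHOUT_DAYS,
    lexicon: Optional[KeywordLexicon] = None,
) -> list[MedicationEpisode]:
    """Merge prescription records into per-patient, per-class episodes.

    Within one patient and class, records sorted by start date merge while
    the gap from the previous usage period's end (or the switch from its
    start, when no stop was documented) is below ``washout_days``; a gap of
    ``washout_days`` or more opens a new episode.  Records for drugs
    outside the two classes are ignored.
    """
    if washout_days <= 0:
        raise ValueError("washout_days must be positive")
    lexicon = lexicon or default_lexicon()

    groups: dict[tuple[str, str], list[PrescriptionRecord]] = {}
    for rec in records:
        cls = drug_class_of(rec.drug_name, lexicon)
        if cls is None:
            continue
        groups.setdefault((rec.patient_id, cls), []).append(rec)

    episodes: list[MedicationEpisode] = []
    for (patient_id, cls), recs in sorted(groups.items()):
        recs = sorted(recs, key=lambda r: (r.start, r.order_date))
        runs: list[list[PrescriptionRecord]] = []
        current: list[PrescriptionRecord] = []
        current_end: Optional[dt.date] = None  # None = open-ended
        for rec in recs:
            if not current:
                current = [rec]
                current_end = rec.reported_stop_date
                continue
            if current_end is None:
                gap = 0  # previous use still ongoing at the switch
            else:
                gap = (rec.start - current_end).days
            if gap < washout_days:
                if current_end is not None and rec.start < current[0].start:
                    raise EpisodeValidationError(
                        "inconsistent overlapping records: "
                        + ", ".join(r.record_id or r.drug_name for r in current + [rec])
                    )
                current.append(rec)
                if rec.reported_stop_date is None:
                    current_end = None
                elif current_end is not None:
                    current_end = max(current_end, rec.reported_stop_date)
                else:
                    current_end = None
            else:
                runs.append(current)
                current = [rec]
                current_end = rec.reported_stop_date
        if current:
            runs.append(current)

        for k, run in enumerate(runs, start=1):
            drugs = tuple(dict.fromkeys(r.drug_name for r in run))
            stops = [r.reported_stop_date for r in run]
            end = None if any(s is None for s in stops) else max(stops)
            flags = frozenset().union(*(r.flags for r in run))
            snri_ends = [r.prior_snri_end_date for r in run if r.prior_snri_end_date]
            episodes.append(
                MedicationEpisode(
                    episode_id=f"{patient_id}-{cls}-{k}",
                    patient_id=patient_id,
                    drug_class=cls,
                    drug_sequence=drugs,
                    start_date=run[0].start,
                    end_date=end,
                    index_date=min(r.order_date for r in run),
                    intolerant=bool(
                        flags & {"discontinued_adverse_event", "allergy_listed"}
                    ),
                    flags=flags,
                    prior_snri_end_date=min(snri_ends) if snri_ends else None,
                )
            )
    return episodes


def apply_exclusions(
    episode: MedicationEpisode,
    followup_dates: Iterable[dt.date] = (),
    washout_days: int = WASHOUT_DAYS,
) -> MedicationEpisode:
    """Apply the study exclusion rules to one episode.

    ``followup_dates`` are the dates of the patient's clinical notes; an
    episode with no documentation after its start has no evaluable
    follow-up.  Returns a copy with status/exclusion_reason set.
    """
    reason: Optional[str] = None
    started_before_index = (episode.index_date - episode.start_date).days
    started_after_index = (episode.start_date - episode.index_date).days
    if started_before_index > EARLY_START_DAYS:
        reason = "early_start"
    elif started_after_index > LATE_START_DAYS:
        reason = "late_start"
    elif (
        episode.drug_class == "SSRI"
        and episode.prior_snri_end_date is not None
        and (episode.start_date - episode.prior_snri_end_date).days < washout_days
    ):
        reason = "snri_carryover"
    elif "start_unknown" in episode.flags:
        reason = "start_unknown"
    elif "record_protected" in episode.flags:
        reason = "record_protected"
    elif "never_started" in episode.flags:
        reason = "never_started"
    elif "discontinued_diagnosis_change" in episode.flags:
        reason = "diagnosis_change"
    elif not any(d > episode.start_date for d in followup_dates):
        reason = "no_followup"

    if reason is None:
        return replace(episode, status="included", exclusion_reason=None)
    return replace(episode, status="excluded", exclusion_reason=reason)
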