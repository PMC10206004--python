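"""Synthetic EMR corpus generation with known ground truth.

Every stage of the scoring pipeline is testable without any real medical
record: the generator emits clinical notes assembled from the lexicon's own
phrases, matching prescription records (one included episode per case) and
optional pre/post cognitive screens, together with the case-level and
comment-level ground truth the pipeline is expected to recover.

The default configuration reproduces the observed case mix of the study
population this package models: 225 SSRI cases (6 N/A, 17 intolerant, 156
improved, 28 no change, 18 worse) and 115 CEI cases (7 N/A, 12 intolerant,
31 improved, 40 no change, 25 worse), with matching diagnosis-group, sex
and age margins.  Category counts are laid down exactly, not sampled;
covariates are sampled from the configured margins.  Free-text realism is
a non-goal: sentences are templates built from lexicon phrases, which is
precisely what makes zero-noise round-trip recovery a meaningful oracle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .annotate import ClinicalNote
from .episodes import PrescriptionRecord
from .lexicon import KeywordLexicon, default_lexicon
from .scoring import CognitiveScoreRecord

__all__ = [
    "ClassMix",
    "CorpusConfig",
    "SyntheticCorpus",
    "DEFAULT_SSRI_MIX",
    "DEFAULT_CEI_MIX",
    "generate_case_truth_table",
    "render_note_corpus",
    "generate_corpus",
    "generate_rater_pair",
]

CATEGORIES = ("na", "intolerance", "improved", "no_change", "worsen")
DIAGNOSIS_GROUPS = ("AD", "VD", "AD+VD", "Others")


@dataclass(frozen=True)
class ClassMix:
    """Case mix for one drug class."""

    category_counts: dict[str, int]
    diagnosis_counts: dict[str, int]
    sex_counts: dict[str, int]
    age_mean: float
    age_sd: float

    @property
    def n_cases(self) -> int:
        return sum(self.category_counts.values())

    def validate(self) -> None:
        bad = set(self.category_counts) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories {sorted(bad)}")
        for counts in (self.category_counts, self.diagnosis_counts, self.sex_counts):
            if any(v < 0 for v in counts.values()):
                raise ValueError("negative count in mix")


DEFAULT_SSRI_MIX = ClassMix(
    category_counts={"na": 6, "intolerance": 17, "improved": 156, "no_change": 28, "worsen": 18},
    diagnosis_counts={"AD": 73, "VD": 42, "AD+VD": 20, "Others": 90},
    sex_counts={"woman": 117, "man": 108},
    age_mean=73.0,
    age_sd=9.7,
)

DEFAULT_CEI_MIX = ClassMix(
    category_counts={"na": 7, "intolerance": 12, "improved": 31, "no_change": 40, "worsen": 25},
    diagnosis_counts={"AD": 54, "VD": 13, "AD+VD": 13, "Others": 35},
    sex_counts={"woman": 55, "man": 60},
    age_mean=74.0,
    age_sd=8.8,
)


@dataclass(frozen=True)
class CorpusConfig:
    """Knobs of the synthetic corpus.

    noise_rate: probability a generated comment omits its direction keyword
    (turning the case unrecoverable) or an extra distractor sentence is
    appended.  cibic_intensity_rate: probability a scorable comment carries
    an intensity modifier (making it gradable on the seven-point scale).
    decline_after_improve_rate: probability an improved case also documents
    a later decline (exercising the improvement-overrides-later-decline
    rule).  mmse_rate: fraction of cognitive-domain cases with pre/post
    cognitive screens whose change sign matches the truth direction.
    """

    mixes: dict[str, ClassMix] = field(
        default_factory=lambda: {"SSRI": DEFAULT_SSRI_MIX, "CEI": DEFAULT_CEI_MIX}
    )
    source_mix: dict[str, float] = field(
        default_factory=lambda: {"clinician": 0.7, "caregiver": 0.2, "patient": 0.1}
    )
    noise_rate: float = 0.0
    cibic_intensity_rate: float = 0.5
    decline_after_improve_rate: float = 0.15
    mmse_rate: float = 0.4
    base_date: dt.date = dt.date(2015, 1, 1)
    start_jitter_days: int = 1460
    comment_mean_days: float = 182.0
    comment_sd_days: float = 45.0
    seed: int = 0

    def validate(self) -> None:
        for mix in self.mixes.values():
            mix.validate()
        for p in (self.noise_rate, self.cibic_intensity_rate,
                  self.decline_after_improve_rate, self.mmse_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not np.isclose(sum(self.source_mix.values()), 1.0):
            raise ValueError("source_mix must sum to 1")


@dataclass(frozen=True)
class SyntheticCorpus:
    truth: pd.DataFrame
    notes: list[ClinicalNote]
    prescriptions: list[PrescriptionRecord]
    cognitive: list[CognitiveScoreRecord]
    comment_truth: pd.DataFrame


def _sample_margin(rng: np.random.Generator, counts: dict[str, int], n: int) -> list[str]:
    labels = sorted(counts)
    total = sum(counts.values())
    probs = [counts[l] / total for l in labels]
    return list(rng.choice(labels, size=n, p=probs))


def generate_case_truth_table(config: CorpusConfig) -> pd.DataFrame:
    """Case-level ground truth: exact category counts, sampled covariates."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    case_no = 0
    for drug_class in sorted(config.mixes):
        mix = config.mixes[drug_class]
        cats: list[str] = []
        for cat in CATEGORIES:
            cats.extend([cat] * mix.category_counts.get(cat, 0))
        perm = rng.permutation(len(cats))
        cats = [cats[i] for i in perm]
        diagnoses = _sample_margin(rng, mix.diagnosis_counts, len(cats))
        sexes = _sample_margin(rng, mix.sex_counts, len(cats))
        ages = np.clip(
            rng.normal(mix.age_mean, mix.age_sd, size=len(cats)), 50, 95
        ).round().astype(int)
        for i, cat in enumerate(cats):
            case_no += 1
            rows.append(
                {
                    "case_id": f"C{case_no:05d}",
                    "patient_id": f"P{case_no:05d}",
                    "drug_class": drug_class,
                    "category": cat,
                    "intolerant": cat == "intolerance",
                    "diagnosis_group": diagnoses[i],
                    "sex": sexes[i],
                    "age": int(ages[i]),
                }
            )
    return pd.DataFrame(rows)


# Sentence templates per (domain, direction).  "{mod}" takes an intensity
# modifier ("" when the comment is not gradable).  All content words are
# lexicon phrases, so zero-noise recovery is by construction.
_TEMPLATES = {
    ("psychiatric", "improve"): (
        "Anxiety {mod}better.",
        "Mood {mod}improved.",
        "Depression {mod}improved.",
        "Agitation now stable.",
    ),
    ("psychiatric", "no_change"): (
        "No change in anxiety.",
        "Mood about the same.",
        "Depression unchanged.",
    ),
    ("psychiatric", "worsen"): (
        "Anxiety {mod}worse.",
        "Agitation {mod}worse.",
        "Mood {mod}worse.",
    ),
    ("cognitive", "improve"): (
        "Memory {mod}better.",
        "Memory {mod}improved.",
        "Recall {mod}improved.",
    ),
    ("cognitive", "no_change"): (
        "Dementia stable.",
        "Memory about the same.",
        "Cognition unchanged.",
    ),
    ("cognitive", "worsen"): (
        "Memory {mod}worse.",
        "Cognition {mod}worse.",
        "Recall {mod}worse.",
    ),
}

# "Agitation now stable." reads as improvement but carries no intensity and
# must never be picked when a gradable sentence is required, so templates
# that cannot take "{mod}" only serve intensity-free comments.
_NEUTRAL_SENTENCES = (
    "Seen in clinic for routine follow up.",
    "Medication refilled at today's visit.",
    "Will return to clinic in three months.",
    "Vitals reviewed and stable today.",
)
# NB: "stable" alone without a symptom cue is not a direction cue, so the
# last neutral sentence stays unscorable by construction.

_INTENSITY_WORDS = {
    "markedly": ("much", "significantly", "markedly"),
    "moderately": ("moderately",),
    "slightly": ("slightly",),
}

_DRUGS = {"SSRI": ("sertraline", "citalopram", "escitalopram"),
          "CEI": ("donepezil", "rivastigmine", "galantamine")}


def _pick_sentence(
    rng: np.random.Generator, domain: str, direction: str, intensity: str
) -> str:
    options = _TEMPLATES[(domain, direction)]
    if intensity != "none":
        options = tuple(o for o in options if "{mod}" in o)
        mod = str(rng.choice(_INTENSITY_WORDS[intensity])) + " "
    else:
        mod = ""
    template = str(rng.choice([o for o in options]))
    return template.replace("{mod}", mod)


def _sample_role(rng: np.random.Generator, source_mix: dict[str, float]) -> str:
    roles = sorted(source_mix)
    probs = [source_mix[r] for r in roles]
    return str(rng.choice(roles, p=probs))


def render_note_corpus(
    truth: pd.DataFrame,
    lexicon: Optional[KeywordLexicon] = None,
    config: Optional[CorpusConfig] = None,
) -> SyntheticCorpus:
    """Materialise notes, prescriptions and cognitive screens for a truth
    table.

    Each case becomes one patient with one prescription run (hence exactly
    one episode).  Scorable cases embed one comment sentence consistent
    with their truth; intolerant cases signal through an adverse-event
    discontinuation flag; N/A cases produce follow-up notes with no
    direction cue.  At a positive noise rate, a comment may drop its
    keyword or gain a distractor sentence.
    """
    lexicon = lexicon or default_lexicon()
    config = config or CorpusConfig()
    config.validate()
    rng = np.random.default_rng(config.seed + 1)

    notes: list[ClinicalNote] = []
    prescriptions: list[PrescriptionRecord] = []
    cognitive: list[CognitiveScoreRecord] = []
    comment_rows = []
    note_no = 0

    def add_note(pid: str, date: dt.date, role: str, text: str) -> str:
        nonlocal note_no
        note_no += 1
        nid = f"N{note_no:06d}"
        notes.append(ClinicalNote(nid, pid, date, role, text))
        return nid

    for row in truth.itertuples(index=False):
        pid = row.patient_id
        drug_class = row.drug_class
        domain = "psychiatric" if drug_class == "SSRI" else "cognitive"
        start = config.base_date + dt.timedelta(
            days=int(rng.integers(0, config.start_jitter_days))
        )
        drug = _DRUGS[drug_class][int(rng.integers(len(_DRUGS[drug_class])))]

        flags = frozenset()
        stop: Optional[dt.date] = None
        if row.category == "intolerance":
            flags = frozenset({"discontinued_adverse_event"})
            stop = start + dt.timedelta(days=int(rng.integers(20, 90)))
        prescriptions.append(
            PrescriptionRecord(
                patient_id=pid,
                drug_name=drug,
                order_date=start,
                reported_start_date=start,
                reported_stop_date=stop,
                flags=flags,
                record_id=f"{row.case_id}-rx",
            )
        )

        # Baseline documentation on the start day.
        add_note(pid, start, "clinician",
                 str(rng.choice(_NEUTRAL_SENTENCES)))

        comment_offset = int(
            np.clip(rng.normal(config.comment_mean_days, config.comment_sd_days),
                    30, 360)
        )
        comment_date = start + dt.timedelta(days=comment_offset)

        if row.category in ("improved", "no_change", "worsen"):
            direction = {"improved": "improve", "no_change": "no_change",
                         "worsen": "worsen"}[row.category]
            intensity = "none"
            if direction != "no_change" and rng.random() < config.cibic_intensity_rate:
                intensity = str(
                    rng.choice(["markedly", "moderately", "slightly"])
                )
            dropped = rng.random() < config.noise_rate
            if dropped:
                text = str(rng.choice(_NEUTRAL_SENTENCES))
            else:
                text = _pick_sentence(rng, domain, direction, intensity)
                if rng.random() < config.noise_rate:
                    text += " " + str(rng.choice(_NEUTRAL_SENTENCES))
            role = _sample_role(rng, config.source_mix)
            nid = add_note(pid, comment_date, role, text)
            if not dropped:
                comment_rows.append(
                    {
                        "note_id": nid,
                        "case_id": row.case_id,
                        "domain": domain,
                        "direction": direction,
                        "intensity": intensity,
                    }
                )
            # Improvement overrides a decline documented later.
            if (
                direction == "improve"
                and not dropped
                and rng.random() < config.decline_after_improve_rate
            ):
                later = comment_date + dt.timedelta(
                    days=int(rng.integers(60, 180))
                )
                nid2 = add_note(
                    pid, later, _sample_role(rng, config.source_mix),
                    _pick_sentence(rng, domain, "worsen", "none"),
                )
                comment_rows.append(
                    {
                        "note_id": nid2,
                        "case_id": row.case_id,
                        "domain": domain,
                        "direction": "worsen",
                        "intensity": "none",
                    }
                )
            if domain == "cognitive" and rng.random() < config.mmse_rate:
                pre = int(rng.integers(18, 27))
                delta = {"improve": 2, "no_change": 0, "worsen": -3}[direction]
                cognitive.append(
                    CognitiveScoreRecord(
                        pid, start - dt.timedelta(days=int(rng.integers(0, 10))),
                        "MMSE", pre,
                    )
                )
                cognitive.append(
                    CognitiveScoreRecord(
                        pid,
                        comment_date + dt.timedelta(days=int(rng.integers(0, 10))),
                        "MMSE", int(np.clip(pre + delta, 0, 30)),
                    )
                )
        else:
            # N/A and intolerant cases: follow-up exists, nothing scorable.
            followup = start + dt.timedelta(days=int(rng.integers(20, 60)))
            add_note(pid, followup, "clinician",
                     str(rng.choice(_NEUTRAL_SENTENCES)))

    comment_truth = pd.DataFrame(
        comment_rows,
        columns=["note_id", "case_id", "domain", "direction", "intensity"],
    )
    return SyntheticCorpus(
        truth=truth.copy(),
        notes=notes,
        prescriptions=prescriptions,
        cognitive=cognitive,
        comment_truth=comment_truth,
    )


def generate_corpus(config: Optional[CorpusConfig] = None) -> SyntheticCorpus:
    """Truth table + rendered corpus in one call."""
    config = config or CorpusConfig()
    truth = generate_case_truth_table(config)
    return render_note_corpus(truth, default_lexicon(), config)


def generate_rater_pair(
    n_units: int,
    disagreement_spec: Optional[dict[tuple[float, float], int]] = None,
    seed: int = 0,
    margins: Optional[dict[float, float]] = None,
) -> np.ndarray:
    """An (n_units x 2) rating matrix with controlled disagreement.

    Rater 1 draws from ``margins`` (probabilities over score codes,
    default weighted toward evaluable scores); rater 2 copies rater 1 and
    then applies each (from_code, to_code) -> count transposition of
    ``disagreement_spec`` to randomly chosen units.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    margins = margins or {0.0: 0.1, 1.0: 0.4, 2.0: 0.3, 3.0: 0.2}
    codes = sorted(margins)
    probs = [margins[c] for c in codes]
    r1 = rng.choice(codes, size=n_units, p=probs)
    r2 = r1.copy()
    for (frm, to), count in (disagreement_spec or {}).items():
        eligible = np.flatnonzero(r1 == frm)
        if count > eligible.size:
            raise ValueError(
                f"cannot move {count} units from {frm}: only "
                f"{eligible.size} available"
            )
        chosen = rng.permutation(eligible)[:count]
        r2[chosen] = to
    return np.column_stack([r1, r2]).astype(float)
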