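"""Evidence prioritization, scale assignment, responder mapping, MMSE change."""

import datetime as dt
import itertools

import pytest

from notescore.annotate import CommentAnnotation
from notescore.episodes import MedicationEpisode
from notescore.scoring import (
    CognitiveScoreRecord,
    EpisodeScore,
    assign_note,
    classify_responder,
    collapse_cibic,
    compute_mmse_change,
    convert_moca_to_mmse,
    score_episode,
    select_prioritized_comment,
    _SYNTHETIC_MOCA_TO_MMSE,
)

D0 = dt.date(2018, 1, 1)


def day(n):
    return D0 + dt.timedelta(days=n)


def episode(drug_class="SSRI", intolerant=False, end=None):
    return MedicationEpisode(
        episode_id="E1",
        patient_id="P1",
        drug_class=drug_class,
        drug_sequence=("sertraline",) if drug_class == "SSRI" else ("donepezil",),
        start_date=day(0),
        end_date=day(end) if end is not None else None,
        index_date=day(0),
        intolerant=intolerant,
    )


def ann(direction, at, domain="psychiatric", role="clinician",
        intensity="none", drugs=frozenset()):
    return CommentAnnotation(
        note_id=f"N{at}",
        patient_id="P1",
        date=day(at),
        author_role=role,
        drug_classes_mentioned=frozenset(drugs),
        domain=domain,
        direction=direction,
        intensity=intensity,
    )


class TestSelectPrioritizedComment:
    def test_improvement_overrides_later_decline(self):
        pool = [ann("improve", 60), ann("worsen", 300)]
        chosen = select_prioritized_comment(pool, episode(), "psychiatric")
        assert chosen.direction == "improve"

    def test_nearest_to_six_months_within_direction(self):
        pool = [ann("no_change", 100), ann("no_change", 400)]
        chosen = select_prioritized_comment(pool, episode(), "psychiatric")
        assert chosen.date == day(100)  # |100-182| < |400-182|

    def test_clinician_beats_patient(self):
        pool = [ann("no_change", 400, role="patient"),
                ann("no_change", 100, role="patient"),
                ann("no_change", 350, role="clinician")]
        chosen = select_prioritized_comment(pool, episode(), "psychiatric")
        assert chosen.author_role == "clinician"
        assert chosen.date == day(350)

    def test_unknown_role_ranked_below_patient(self):
        pool = [ann("improve", 180, role="unknown"),
                ann("improve", 350, role="patient")]
        chosen = select_prioritized_comment(pool, episode(), "psychiatric")
        assert chosen.author_role == "patient"

    def test_mmse_matched_date_wins_for_cognitive(self):
        pool = [ann("worsen", 180, domain="cognitive"),
                ann("worsen", 320, domain="cognitive")]
        chosen = select_prioritized_comment(
            pool, episode("CEI"), "cognitive", mmse_change_dates=[day(325)]
        )
        assert chosen.date == day(320)

    def test_mmse_dates_ignored_for_psychiatric(self):
        pool = [ann("worsen", 180), ann("worsen", 320)]
        chosen = select_prioritized_comment(
            pool, episode(), "psychiatric", mmse_change_dates=[day(325)]
        )
        assert chosen.date == day(180)

    def test_tie_breaks_to_earlier_date(self):
        pool = [ann("improve", 132), ann("improve", 232)]  # both 50 days off 182
        chosen = select_prioritized_comment(pool, episode(), "psychiatric")
        assert chosen.date == day(132)

    def test_comment_outside_episode_window_ignored(self):
        # episode ended day 100; washout carryover accepts up to day 190
        pool = [ann("improve", 195)]
        assert select_prioritized_comment(pool, episode(end=100), "psychiatric") is None
        pool = [ann("improve", 185)]
        assert select_prioritized_comment(pool, episode(end=100), "psychiatric") is not None


class TestAssignNote:
    def test_unclassified_counts_toward_default_domain_only(self):
        comments = [ann("improve", 180, domain="unclassified", drugs={"CEI"})]
        scores = score_episode(episode("CEI"), comments)
        assert scores["cognitive"].note_value == 1.0
        assert scores["psychiatric"].note_value == 0.0

    def test_unclassified_other_class_not_counted(self):
        comments = [ann("improve", 180, domain="unclassified", drugs={"SSRI"})]
        scores = score_episode(episode("CEI"), comments)
        assert scores["cognitive"].note_value == 0.0

    def test_intolerant_overrides_comments(self):
        comments = [ann("improve", 180)]
        s = assign_note(episode(intolerant=True), comments, "psychiatric")
        assert s.note_value == 0.5
        assert s.cibic_value == 0.5

    def test_no_annotations_is_na(self):
        scores = score_episode(episode(), [])
        assert all(s.note_value == 0.0 for s in scores.values())

    @pytest.mark.parametrize(
        "direction,intensity,note,cibic",
        [
            ("improve", "markedly", 1.0, 1),
            ("improve", "moderately", 1.0, 2),
            ("improve", "slightly", 1.0, 3),
            ("improve", "none", 1.0, 0),     # ungradable: CIBIC-plus N/A
            ("no_change", "none", 2.0, 4),
            ("worsen", "slightly", 3.0, 5),
            ("worsen", "moderately", 3.0, 6),
            ("worsen", "markedly", 3.0, 7),
            ("worsen", "none", 3.0, 0),
        ],
    )
    def test_scale_mapping(self, direction, intensity, note, cibic):
        s = assign_note(
            episode(), [ann(direction, 180, intensity=intensity)], "psychiatric"
        )
        assert (s.note_value, s.cibic_value) == (note, cibic)

    def test_collapsed_cibic_equals_note_when_gradable(self):
        for cibic in (1, 2, 3, 4, 5, 6, 7):
            note = {1: 1.0, 2: 1.0, 3: 1.0, 4: 2.0, 5: 3.0, 6: 3.0, 7: 3.0}[cibic]
            assert collapse_cibic(cibic) == note

    def test_scale_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            EpisodeScore("E1", "cognitive", 1.0, 5)


class TestClassifyResponder:
    @pytest.mark.parametrize(
        "drug_class,note,category",
        [
            ("SSRI", 1.0, "responder"),
            ("SSRI", 2.0, "non_responder"),
            ("SSRI", 3.0, "non_responder"),
            ("SSRI", 0.5, "intolerant"),
            ("SSRI", 0.0, "not_evaluable"),
            ("CEI", 1.0, "responder"),
            ("CEI", 2.0, "responder"),   # cognitive stability counts as response
            ("CEI", 3.0, "non_responder"),
            ("CEI", 0.5, "intolerant"),
            ("CEI", 0.0, "not_evaluable"),
        ],
    )
    def test_mapping(self, drug_class, note, category):
        domain = "psychiatric" if drug_class == "SSRI" else "cognitive"
        cibic = {0.0: 0.0, 0.5: 0.5, 1.0: 0, 2.0: 4, 3.0: 0}[note]
        score = EpisodeScore("E1", domain, note, cibic)
        assert classify_responder(score, drug_class).category == category

    def test_domain_mismatch_is_contract_error(self):
        score = EpisodeScore("E1", "cognitive", 1.0, 0)
        with pytest.raises(ValueError, match="psychiatric"):
            classify_responder(score, "SSRI")


class TestMocaConversion:
    def test_endpoints_and_bundled_rows(self):
        assert convert_moca_to_mmse(30) == 30
        assert convert_moca_to_mmse(0) == _SYNTHETIC_MOCA_TO_MMSE[0]
        assert convert_moca_to_mmse(15) == _SYNTHETIC_MOCA_TO_MMSE[15]

    def test_monotone_and_in_range(self):
        values = [convert_moca_to_mmse(i) for i in range(31)]
        assert values == sorted(values)
        assert all(0 <= v <= 30 for v in values)

    @pytest.mark.parametrize("bad", [-1, 31])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            convert_moca_to_mmse(bad)

    def test_mmse_identity_path(self):
        rec = CognitiveScoreRecord("P1", day(0), "MMSE", 24)
        assert rec.mmse_equivalent == 24


class TestMmseChange:
    def test_simple_delta(self):
        records = [
            CognitiveScoreRecord("P1", day(-3), "MMSE", 24),
            CognitiveScoreRecord("P1", day(185), "MMSE", 26),
        ]
        assert compute_mmse_change(records, episode(), day(180)) == 2

    def test_missing_pre_returns_none(self):
        records = [CognitiveScoreRecord("P1", day(30), "MMSE", 24),
                   CognitiveScoreRecord("P1", day(185), "MMSE", 26)]
        assert compute_mmse_change(records, episode(), day(180)) is None

    def test_other_patient_records_ignored(self):
        records = [CognitiveScoreRecord("P2", day(0), "MMSE", 24),
                   CognitiveScoreRecord("P2", day(180), "MMSE", 26)]
        assert compute_mmse_change(records, episode(), day(180)) is None

    def test_window_inclusive_of_day_14(self):
        records = [
            CognitiveScoreRecord("P1", day(-14), "MMSE", 20),
            CognitiveScoreRecord("P1", day(194), "MMSE", 25),
        ]
        assert compute_mmse_change(records, episode(), day(180)) == 5

    def test_nearest_record_exhaustive(self):
        """Nearest-in-window selection agrees with brute force over all
        two-candidate offset layouts."""
        for pre_offs in itertools.permutations([-2, 10, 20], 2):
            for post_offs in itertools.permutations([3, -9, 16], 2):
                records = [
                    CognitiveScoreRecord("P1", day(o), "MMSE", 20 + i)
                    for i, o in enumerate(pre_offs)
                ] + [
                    CognitiveScoreRecord("P1", day(180 + o), "MMSE", 25 + i)
                    for i, o in enumerate(post_offs)
                ]
                got = compute_mmse_change(records, episode(), day(180))
                in_pre = [r for r in records
                          if abs((r.date - day(0)).days) <= 14]
                in_post = [r for r in records
                           if abs((r.date - day(180)).days) <= 14]
                if not in_pre or not in_post:
                    assert got is None
                    continue
                pre = min(in_pre, key=lambda r: (abs((r.date - day(0)).days), r.date))
                post = min(in_post, key=lambda r: (abs((r.date - day(180)).days), r.date))
                assert got == post.raw_score - pre.raw_score
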