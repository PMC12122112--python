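"""Staged routing rules, whole-patient triage and the follow-up ratchet."""

import itertools

import pytest

from lmscore.errors import ValidationError
from lmscore.score_model import Assessment, ScorePart
from lmscore.triage import (
    Annotation,
    Disposition,
    FollowUpEvent,
    Grade,
    Stage2Route,
    apply_follow_up,
    grade_from_history,
    replay_trace,
    stage2_route,
    stage3_route,
    triage_patient,
)


def vector_with_score(part: ScorePart, target: int, table) -> Assessment:
    """Greedily build a valid item vector whose sum equals ``target``."""
    points, remaining = {}, target
    for item in table.items(part):
        take = max(p for p in item.allowed_points if p <= remaining)
        points[item.item_id] = take
        remaining -= take
    assert remaining == 0, f"cannot reach score {target} for {part}"
    return Assessment(part, points, table)


class TestStageRules:
    @pytest.mark.parametrize(
        "score, grade",
        [(0, Grade.MILD), (3, Grade.MILD), (4, Grade.MODERATE), (9, Grade.MODERATE),
         (10, Grade.SEVERE), (15, Grade.SEVERE)],
    )
    def test_grade_boundaries(self, score, grade):
        assert grade_from_history(score) is grade

    @pytest.mark.parametrize(
        "score, route",
        [(0, Stage2Route.CONSERVATIVE), (3, Stage2Route.CONSERVATIVE),
         (4, Stage2Route.STAGE3), (6, Stage2Route.STAGE3), (9, Stage2Route.STAGE3),
         (10, Stage2Route.SUPRAGLOTTOPLASTY), (13, Stage2Route.SUPRAGLOTTOPLASTY)],
    )
    def test_stage2_boundaries(self, score, route):
        assert stage2_route(score) is route

    @pytest.mark.parametrize(
        "score, disposition",
        [(0, Disposition.WATCHFUL_WAITING), (5, Disposition.WATCHFUL_WAITING),
         (6, Disposition.SUPRAGLOTTOPLASTY), (10, Disposition.SUPRAGLOTTOPLASTY)],
    )
    def test_stage3_boundaries(self, score, disposition):
        assert stage3_route(score) is disposition

    @pytest.mark.parametrize(
        "fn, bad",
        [(grade_from_history, -1), (grade_from_history, 16),
         (stage2_route, 14), (stage3_route, 11), (grade_from_history, 3.5)],
    )
    def test_out_of_range_scores_rejected(self, fn, bad):
        with pytest.raises(ValidationError):
            fn(bad)

    def test_every_composite_triple_has_exactly_one_disposition(self, table):
        """Completeness: all (h, e, i) score triples route without gaps."""
        for h, e, i in itertools.product(range(16), range(14), range(11)):
            trace = triage_patient(
                vector_with_score(ScorePart.HISTORY, h, table),
                vector_with_score(ScorePart.EXAM, e, table),
                vector_with_score(ScorePart.INVESTIGATION, i, table),
            )
            assert trace.disposition in Disposition

    def test_disposition_monotone_in_each_score(self, table):
        """Raising any part score never lowers the ordered disposition."""
        def dispo(h, e, i):
            return triage_patient(
                vector_with_score(ScorePart.HISTORY, h, table),
                vector_with_score(ScorePart.EXAM, e, table),
                vector_with_score(ScorePart.INVESTIGATION, i, table),
            ).disposition

        grid = {
            (h, e, i): dispo(h, e, i)
            for h, e, i in itertools.product(range(16), range(14), range(11))
        }
        for (h, e, i), d in grid.items():
            for nxt in ((h + 1, e, i), (h, e + 1, i), (h, e, i + 1)):
                if nxt in grid:
                    assert grid[nxt].rank >= d.rank, (h, e, i, nxt)


class TestTriagePatient:
    def test_mild_is_conservative_without_exam(self, table):
        trace = triage_patient(vector_with_score(ScorePart.HISTORY, 2, table))
        assert trace.grade is Grade.MILD
        assert trace.disposition is Disposition.CONSERVATIVE
        assert trace.follow_up_months == (1, 2, 3)  # monthly review for three months

    def test_moderate_high_exam_goes_to_surgery_via_stage2(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 6, table),
            vector_with_score(ScorePart.EXAM, 11, table),
        )
        assert trace.disposition is Disposition.SUPRAGLOTTOPLASTY
        assert [r.stage for r in trace.records] == [1, 2]

    def test_moderate_mid_exam_routes_on_investigation(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 6, table),
            vector_with_score(ScorePart.EXAM, 6, table),
            vector_with_score(ScorePart.INVESTIGATION, 7, table),
        )
        assert trace.disposition is Disposition.SUPRAGLOTTOPLASTY
        assert [r.stage for r in trace.records] == [1, 2, 3]

    def test_severe_is_surgical_regardless_of_baseline_scores(self, table):
        """Stage 2/3 scores of a severe patient are baseline only."""
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 12, table),
            vector_with_score(ScorePart.EXAM, 8, table),
            vector_with_score(ScorePart.INVESTIGATION, 4, table),
        )
        assert trace.disposition is Disposition.SUPRAGLOTTOPLASTY
        assert all(r.rule == "preop_baseline" for r in trace.records if r.stage > 1)

    @pytest.mark.parametrize("history_score, missing_stage", [(6, 2), (12, 2)])
    def test_missing_exam_error_names_stage(self, table, history_score, missing_stage):
        with pytest.raises(ValidationError, match=f"stage {missing_stage}"):
            triage_patient(vector_with_score(ScorePart.HISTORY, history_score, table))

    def test_missing_investigation_error_names_stage3(self, table):
        with pytest.raises(ValidationError, match="stage 3"):
            triage_patient(
                vector_with_score(ScorePart.HISTORY, 6, table),
                vector_with_score(ScorePart.EXAM, 6, table),
            )

    def test_wrong_part_rejected(self, table):
        with pytest.raises(ValidationError, match="expected a exam"):
            triage_patient(
                vector_with_score(ScorePart.HISTORY, 6, table),
                vector_with_score(ScorePart.HISTORY, 6, table),
            )


class TestFollowUp:
    def _mild_trace(self, table):
        return triage_patient(
            vector_with_score(ScorePart.HISTORY, 2, table), patient_id="p1"
        )

    def test_mild_escalation_with_low_exam_stays_conservative(self, table):
        trace = self._mild_trace(table)
        event = FollowUpEvent(
            "p1", 1,
            history=vector_with_score(ScorePart.HISTORY, 5, table),
            exam=vector_with_score(ScorePart.EXAM, 3, table),
        )
        updated = apply_follow_up(trace, event)
        assert updated.disposition is Disposition.CONSERVATIVE
        assert updated.grade is Grade.MODERATE
        assert updated.baseline_grade is Grade.MILD

    def test_escalation_to_severe_band_means_surgery(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 6, table),
            vector_with_score(ScorePart.EXAM, 6, table),
            vector_with_score(ScorePart.INVESTIGATION, 4, table),
            patient_id="p2",
        )
        assert trace.disposition is Disposition.WATCHFUL_WAITING
        event = FollowUpEvent(
            "p2", 3, history=vector_with_score(ScorePart.HISTORY, 11, table)
        )
        updated = apply_follow_up(trace, event)
        assert updated.disposition is Disposition.SUPRAGLOTTOPLASTY

    def test_ratchet_disposition_never_decreases(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 6, table),
            vector_with_score(ScorePart.EXAM, 6, table),
            vector_with_score(ScorePart.INVESTIGATION, 4, table),
            patient_id="p3",
        )
        improved = FollowUpEvent(
            "p3", 2, history=vector_with_score(ScorePart.HISTORY, 1, table)
        )
        updated = apply_follow_up(trace, improved)
        assert updated.disposition is Disposition.WATCHFUL_WAITING  # not downgraded

    def test_carry_forward_missing_exam_warns(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 6, table),
            vector_with_score(ScorePart.EXAM, 2, table),
            patient_id="p4",
        )
        event = FollowUpEvent(
            "p4", 2, history=vector_with_score(ScorePart.HISTORY, 7, table)
        )
        with pytest.warns(UserWarning, match="carrying forward"):
            updated = apply_follow_up(trace, event)
        assert updated.disposition is Disposition.CONSERVATIVE

    def test_postoperative_compromise_adds_tracheostomy(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 12, table),
            vector_with_score(ScorePart.EXAM, 8, table),
            vector_with_score(ScorePart.INVESTIGATION, 4, table),
            patient_id="p5",
        )
        event = FollowUpEvent("p5", 1, event_type="postoperative_airway_compromise")
        updated = apply_follow_up(trace, event)
        assert Annotation.TRACHEOSTOMY in updated.annotations
        assert updated.disposition is Disposition.SUPRAGLOTTOPLASTY

    def test_postoperative_event_requires_surgical_patient(self, table):
        trace = self._mild_trace(table)
        event = FollowUpEvent("p1", 1, event_type="postoperative_airway_compromise")
        with pytest.raises(ValidationError, match="non-surgical"):
            apply_follow_up(trace, event)

    def test_event_for_wrong_patient_rejected(self, table):
        trace = self._mild_trace(table)
        event = FollowUpEvent(
            "ghost", 1, history=vector_with_score(ScorePart.HISTORY, 2, table)
        )
        with pytest.raises(ValidationError, match="unknown patient"):
            apply_follow_up(trace, event)

    def test_visit_outside_horizon_rejected(self, table):
        trace = self._mild_trace(table)
        event = FollowUpEvent(
            "p1", 9, history=vector_with_score(ScorePart.HISTORY, 2, table)
        )
        with pytest.raises(ValidationError, match="horizon"):
            apply_follow_up(trace, event)


class TestTraceAudit:
    def test_replay_reproduces_disposition(self, table):
        """Replaying the recorded rules of any trace gives its disposition."""
        cases = [
            (2, None, None),
            (6, 2, None),
            (6, 6, 4),
            (6, 6, 7),
            (6, 11, 3),
            (12, 8, 4),
        ]
        for h, e, i in cases:
            trace = triage_patient(
                vector_with_score(ScorePart.HISTORY, h, table),
                vector_with_score(ScorePart.EXAM, e, table) if e is not None else None,
                vector_with_score(ScorePart.INVESTIGATION, i, table) if i is not None else None,
            )
            assert replay_trace(trace) is trace.disposition

    def test_replay_covers_follow_up_records(self, table):
        trace = triage_patient(
            vector_with_score(ScorePart.HISTORY, 2, table), patient_id="p1"
        )
        event = FollowUpEvent(
            "p1", 1,
            history=vector_with_score(ScorePart.HISTORY, 5, table),
            exam=vector_with_score(ScorePart.EXAM, 3, table),
        )
        updated = apply_follow_up(trace, event)
        assert replay_trace(updated) is updated.disposition
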