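"""Three-stage management algorithm and follow-up state machine.

Stage 1 grades every patient from the history/symptom score (mild < 4,
moderate 4-9, severe > 9).  Mild patients are managed conservatively
with monthly review; moderate patients enter stage 2, where the
examination score routes them to conservative care (< 4), directly to
supraglottoplasty (> 9), or on to stage 3 (4-9); stage 3 routes on the
investigation score (watchful waiting if <= 5, surgery otherwise).
Severe patients are surgical candidates from stage 1 — their
examination and investigation scores are recorded only as the
preoperative baseline and never alter the disposition.

Follow-up is event-driven and deterministic: reassessment events
re-grade from the new history score (a transition into a higher band
re-enters the algorithm at the corresponding stage), and scripted
clinical events add annotations such as tracheostomy.  Disposition
severity is a ratchet: it never decreases within the follow-up horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

from .errors import ValidationError
from .score_model import Assessment, ScorePart, default_config

__all__ = [
    "Grade",
    "Disposition",
    "Annotation",
    "Stage2Route",
    "StageRecord",
    "TriageTrace",
    "FollowUpEvent",
    "grade_from_history",
    "stage2_route",
    "stage3_route",
    "triage_patient",
    "apply_follow_up",
    "replay_trace",
]


class Grade(Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        return ("mild", "moderate", "severe").index(self.value)

    def __lt__(self, other: "Grade") -> bool:
        return self.rank < other.rank


class Disposition(Enum):
    CONSERVATIVE = "conservative"
    WATCHFUL_WAITING = "watchful_waiting"
    SUPRAGLOTTOPLASTY = "supraglottoplasty"

    @property
    def rank(self) -> int:
        return ("conservative", "watchful_waiting", "supraglottoplasty").index(self.value)

    def __lt__(self, other: "Disposition") -> bool:
        return self.rank < other.rank


class Annotation(str, Enum):
    TRACHEOSTOMY = "tracheostomy"
    ADJUNCT_PROCEDURE = "adjunct_procedure"


class Stage2Route(str, Enum):
    CONSERVATIVE = "conservative"
    STAGE3 = "stage3"
    SUPRAGLOTTOPLASTY = "supraglottoplasty"


@dataclass(frozen=True)
class StageRecord:
    """One fired rule: which stage, the score it saw, what it decided."""

    stage: int
    score: int
    rule: str
    route: str
    visit_month: int = 0


@dataclass(frozen=True)
class TriageTrace:
    """The audited path of one patient through the algorithm.

    Immutable; follow-up events produce a new trace with appended
    records.  ``replay_trace`` re-derives the disposition from the
    recorded rules as an audit check.
    """

    patient_id: str
    grade: Grade
    disposition: Disposition
    records: tuple[StageRecord, ...]
    annotations: frozenset[Annotation] = frozenset()
    baseline_grade: Grade | None = None
    follow_up_months: tuple[int, ...] = ()
    horizon_months: int = 6

    def __post_init__(self) -> None:
        stages = [r.stage for r in self.records if r.visit_month == 0]
        if stages != sorted(stages):
            raise ValidationError(
                f"trace {self.patient_id}: baseline stages out of order {stages}"
            )

    @property
    def post_surgical(self) -> bool:
        return self.disposition is Disposition.SUPRAGLOTTOPLASTY

    def last_score(self, stage: int) -> int | None:
        for rec in reversed(self.records):
            if rec.stage == stage:
                return rec.score
        return None


@dataclass(frozen=True)
class FollowUpEvent:
    """A follow-up visit or scripted clinical event for one patient."""

    patient_id: str
    visit_month: int
    event_type: str = "reassessment"
    history: Assessment | None = None
    exam: Assessment | None = None
    investigation: Assessment | None = None
    note: str = ""

    EVENT_TYPES = ("reassessment", "postoperative_airway_compromise", "sal_tracheostomy")

    def __post_init__(self) -> None:
        if self.event_type not in self.EVENT_TYPES:
            raise ValidationError(f"unknown event type {self.event_type!r}")
        if self.event_type == "reassessment" and self.history is None:
            raise ValidationError(
                f"reassessment event for {self.patient_id} must carry a new history assessment"
            )


def _thresholds() -> dict:
    return default_config()["thresholds"]


def grade_from_history(score: int) -> Grade:
    """History/symptom score (0-15) -> severity grade."""
    score = _check_range("history score", score, 0, 15)
    bands = _thresholds()["grade_bands"]
    for name in ("mild", "moderate", "severe"):
        lo, hi = bands[name]
        if lo <= score <= hi:
            return Grade(name)
    raise ValidationError(f"history score {score} not covered by grade bands")


def stage2_route(exam_score: int) -> Stage2Route:
    """Examination score (0-13) -> stage-2 route for a moderate patient."""
    score = _check_range("exam score", exam_score, 0, 13)
    bands = _thresholds()["exam_bands"]
    if score <= bands["conservative"][1]:
        return Stage2Route.CONSERVATIVE
    if score <= bands["stage3"][1]:
        return Stage2Route.STAGE3
    return Stage2Route.SUPRAGLOTTOPLASTY


def stage3_route(investigation_score: int) -> Disposition:
    """Investigation score (0-10) -> watchful waiting (<= 5) or surgery."""
    score = _check_range("investigation score", investigation_score, 0, 10)
    if score <= _thresholds()["investigation_watchful_max"]:
        return Disposition.WATCHFUL_WAITING
    return Disposition.SUPRAGLOTTOPLASTY


def _check_range(name: str, score: object, lo: int, hi: int) -> int:
    try:
        value = int(score)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise ValidationError(f"{name}: expected an integer, got {score!r}") from None
    if value != score:
        raise ValidationError(f"{name}: expected an integer, got {score!r}")
    if not lo <= value <= hi:
        raise ValidationError(f"{name}: {value} outside [{lo}, {hi}]")
    return value


def _require(assessment: Assessment | None, part: ScorePart, stage: int, patient_id: str) -> Assessment:
    if assessment is None:
        raise ValidationError(
            f"patient {patient_id}: stage {stage} requires a {part.value} assessment"
        )
    if assessment.part is not part:
        raise ValidationError(
            f"patient {patient_id}: stage {stage} expected a {part.value} assessment, "
            f"got {assessment.part.value}"
        )
    return assessment


def triage_patient(
    history: Assessment,
    exam: Assessment | None = None,
    investigation: Assessment | None = None,
    patient_id: str = "anonymous",
) -> TriageTrace:
    """Run one patient through stages 1-3 and return the audited trace.

    The examination assessment is required for moderate and severe
    grades; the investigation assessment is required whenever the
    disposition depends on it (stage-3 routing) and is recorded as the
    preoperative baseline for surgical candidates when supplied.
    """
    history = _require(history, ScorePart.HISTORY, 1, patient_id)
    grade = grade_from_history(history.score)
    records = [StageRecord(1, history.score, f"grade_{grade.value}", grade.value)]
    follow_up: tuple[int, ...] = ()
    cfg = default_config()["follow_up"]

    if grade is Grade.MILD:
        disposition = Disposition.CONSERVATIVE
        follow_up = tuple(range(1, cfg["mild_monthly_visits"] + 1))
    elif grade is Grade.MODERATE:
        exam = _require(exam, ScorePart.EXAM, 2, patient_id)
        route = stage2_route(exam.score)
        records.append(StageRecord(2, exam.score, f"stage2_{route.value}", route.value))
        if route is Stage2Route.CONSERVATIVE:
            disposition = Disposition.CONSERVATIVE
        elif route is Stage2Route.SUPRAGLOTTOPLASTY:
            disposition = Disposition.SUPRAGLOTTOPLASTY
            if investigation is not None:
                investigation = _require(investigation, ScorePart.INVESTIGATION, 3, patient_id)
                records.append(
                    StageRecord(3, investigation.score, "preop_baseline", disposition.value)
                )
        else:
            investigation = _require(investigation, ScorePart.INVESTIGATION, 3, patient_id)
            disposition = stage3_route(investigation.score)
            records.append(
                StageRecord(
                    3,
                    investigation.score,
                    f"stage3_{disposition.value}",
                    disposition.value,
                )
            )
    else:  # severe: surgical candidate, stages 2-3 are baseline only
        disposition = Disposition.SUPRAGLOTTOPLASTY
        exam = _require(exam, ScorePart.EXAM, 2, patient_id)
        records.append(StageRecord(2, exam.score, "preop_baseline", disposition.value))
        if investigation is not None:
            investigation = _require(investigation, ScorePart.INVESTIGATION, 3, patient_id)
            records.append(
                StageRecord(3, investigation.score, "preop_baseline", disposition.value)
            )

    return TriageTrace(
        patient_id=patient_id,
        grade=grade,
        disposition=disposition,
        records=tuple(records),
        baseline_grade=grade,
        follow_up_months=follow_up,
        horizon_months=cfg["horizon_months"],
    )


def apply_follow_up(trace: TriageTrace, event: FollowUpEvent) -> TriageTrace:
    """Apply one follow-up event, returning the updated trace.

    Reassessments re-grade from the new history score; missing exam or
    investigation assessments are carried forward from the last recorded
    visit with a warning.  Disposition severity never decreases.
    Scripted events (postoperative airway compromise, synchronous-lesion
    management requiring tracheostomy) add annotations.
    """
    if event.patient_id != trace.patient_id:
        raise ValidationError(
            f"event for unknown patient {event.patient_id!r} "
            f"(trace belongs to {trace.patient_id!r})"
        )
    if not 0 <= event.visit_month <= trace.horizon_months:
        raise ValidationError(
            f"patient {trace.patient_id}: visit month {event.visit_month} outside "
            f"follow-up horizon 0-{trace.horizon_months}"
        )

    if event.event_type == "postoperative_airway_compromise":
        if not trace.post_surgical:
            raise ValidationError(
                f"patient {trace.patient_id}: postoperative airway compromise "
                "recorded for a non-surgical patient"
            )
        return replace(trace, annotations=trace.annotations | {Annotation.TRACHEOSTOMY})

    if event.event_type == "sal_tracheostomy":
        if not trace.post_surgical:
            raise ValidationError(
                f"patient {trace.patient_id}: synchronous-lesion tracheostomy "
                "recorded for a non-surgical patient"
            )
        return replace(
            trace,
            annotations=trace.annotations
            | {Annotation.TRACHEOSTOMY, Annotation.ADJUNCT_PROCEDURE},
        )

    # reassessment
    if trace.post_surgical:
        raise ValidationError(
            f"patient {trace.patient_id}: reassessment after surgery is not part of "
            "the algorithm (only postoperative complications are recorded)"
        )
    history = _require(event.history, ScorePart.HISTORY, 1, trace.patient_id)
    new_grade = grade_from_history(history.score)
    month = event.visit_month
    records = list(trace.records)
    records.append(
        StageRecord(1, history.score, f"regrade_{new_grade.value}", new_grade.value, month)
    )

    if new_grade is Grade.SEVERE:
        new_disposition = Disposition.SUPRAGLOTTOPLASTY
    elif new_grade is Grade.MODERATE:
        exam = event.exam
        if exam is None:
            carried = trace.last_score(2)
            if carried is None:
                raise ValidationError(
                    f"patient {trace.patient_id}: stage 2 requires an exam assessment "
                    f"at the month-{month} reassessment"
                )
            warnings.warn(
                f"patient {trace.patient_id}: no exam at month {month}; "
                "carrying forward the last examination score",
                stacklevel=2,
            )
            exam_score = carried
        else:
            exam_score = _require(exam, ScorePart.EXAM, 2, trace.patient_id).score
        route = stage2_route(exam_score)
        records.append(
            StageRecord(2, exam_score, f"stage2_{route.value}", route.value, month)
        )
        if route is Stage2Route.CONSERVATIVE:
            new_disposition = Disposition.CONSERVATIVE
        elif route is Stage2Route.SUPRAGLOTTOPLASTY:
            new_disposition = Disposition.SUPRAGLOTTOPLASTY
        else:
            inv = event.investigation
            if inv is None:
                carried = trace.last_score(3)
                if carried is None:
                    raise ValidationError(
                        f"patient {trace.patient_id}: stage 3 requires an investigation "
                        f"assessment at the month-{month} reassessment"
                    )
                warnings.warn(
                    f"patient {trace.patient_id}: no investigation at month {month}; "
                    "carrying forward the last investigation score",
                    stacklevel=2,
                )
                inv_score = carried
            else:
                inv_score = _require(inv, ScorePart.INVESTIGATION, 3, trace.patient_id).score
            new_disposition = stage3_route(inv_score)
            records.append(
                StageRecord(3, inv_score, f"stage3_{new_disposition.value}",
                            new_disposition.value, month)
            )
    else:
        new_disposition = Disposition.CONSERVATIVE

    final = max(trace.disposition, new_disposition, key=lambda d: d.rank)
    return replace(
        trace,
        grade=max(trace.grade, new_grade, key=lambda g: g.rank),
        disposition=final,
        records=tuple(records),
    )


def replay_trace(trace: TriageTrace) -> Disposition:
    """Re-derive the disposition from the recorded rules (audit check).

    Walks the records in order, reapplying the routing function for each
    recorded score, ratcheting across follow-up visits exactly as the
    engine does.
    """
    disposition: Disposition | None = None
    months = sorted({r.visit_month for r in trace.records})
    for month in months:
        visit = [r for r in trace.records if r.visit_month == month]
        visit_disposition: Disposition | None = None
        grade: Grade | None = None
        for rec in visit:
            if rec.stage == 1:
                grade = grade_from_history(rec.score)
                if grade is Grade.SEVERE:
                    visit_disposition = Disposition.SUPRAGLOTTOPLASTY
                elif grade is Grade.MILD:
                    visit_disposition = Disposition.CONSERVATIVE
            elif rec.stage == 2 and rec.rule != "preop_baseline":
                route = stage2_route(rec.score)
                if route is Stage2Route.CONSERVATIVE:
                    visit_disposition = Disposition.CONSERVATIVE
                elif route is Stage2Route.SUPRAGLOTTOPLASTY:
                    visit_disposition = Disposition.SUPRAGLOTTOPLASTY
            elif rec.stage == 3 and rec.rule != "preop_baseline":
                visit_disposition = stage3_route(rec.score)
        if visit_disposition is None:
            continue
        if disposition is None:
            disposition = visit_disposition
        else:
            disposition = max(disposition, visit_disposition, key=lambda d: d.rank)
    if disposition is None:
        raise ValidationError(f"trace {trace.patient_id}: no routing records to replay")
    return disposition
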