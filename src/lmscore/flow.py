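"""Whole-cohort patient flow: triage everyone, apply events, count nodes.

Produces the flow summary mirroring the study's patient-flow figure:
grade counts at stage 1, how many patients each subsequent score stage
was applied to, the routing subgroups, final dispositions and scripted
outcomes (follow-up escalations, tracheostomies).  Percentages are
emitted at both printed precisions (one and two decimals, half-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .io import assessments_from_row
from .score_model import ScoreTable, default_table
from .triage import (
    Annotation,
    Disposition,
    FollowUpEvent,
    Grade,
    TriageTrace,
    apply_follow_up,
    triage_patient,
)

__all__ = ["FlowSummary", "run_cohort_flow", "triage_cohort", "render_report"]


def _pct(count: int, total: int, places: int) -> float:
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-places)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class FlowSummary:
    """Per-node patient counts through the staged algorithm."""

    total: int
    graded: Mapping[str, int]
    graded_pct_1dp: Mapping[str, float]
    graded_pct_2dp: Mapping[str, float]
    exam_stage_applied: int
    exam_subgroups_moderate: Mapping[str, int]  # below_4 / from_4_to_9 / above_9
    investigation_stage_applied: int
    investigation_subgroups_stage3: Mapping[str, int]  # at_most_5 / above_5
    dispositions: Mapping[str, int]
    dispositions_pct_1dp: Mapping[str, float]
    follow_up_reassessed: int
    follow_up_escalations: int
    tracheostomies: int
    mild_baseline_surgical: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "graded": dict(self.graded),
            "graded_pct_1dp": dict(self.graded_pct_1dp),
            "graded_pct_2dp": dict(self.graded_pct_2dp),
            "exam_stage_applied": self.exam_stage_applied,
            "exam_subgroups_moderate": dict(self.exam_subgroups_moderate),
            "investigation_stage_applied": self.investigation_stage_applied,
            "investigation_subgroups_stage3": dict(self.investigation_subgroups_stage3),
            "dispositions": dict(self.dispositions),
            "dispositions_pct_1dp": dict(self.dispositions_pct_1dp),
            "follow_up_reassessed": self.follow_up_reassessed,
            "follow_up_escalations": self.follow_up_escalations,
            "tracheostomies": self.tracheostomies,
            "mild_baseline_surgical": self.mild_baseline_surgical,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FlowSummary":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlowSummary):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def triage_cohort(
    cohort: pd.DataFrame,
    events: Sequence[FollowUpEvent] = (),
    table: ScoreTable | None = None,
) -> list[TriageTrace]:
    """Triage every cohort row, then apply its follow-up events in order."""
    table = table or default_table()
    traces: dict[str, TriageTrace] = {}
    for _, row in cohort.iterrows():
        pid = str(row["patient_id"])
        history, exam, investigation = assessments_from_row(row, table)
        traces[pid] = triage_patient(history, exam, investigation, patient_id=pid)
    for event in sorted(events, key=lambda e: e.visit_month):
        if event.patient_id not in traces:
            raise ValidationError(f"event references unknown patient {event.patient_id!r}")
        traces[event.patient_id] = apply_follow_up(traces[event.patient_id], event)
    return list(traces.values())


def run_cohort_flow(
    cohort: pd.DataFrame,
    events: Sequence[FollowUpEvent] = (),
    table: ScoreTable | None = None,
) -> tuple[FlowSummary, list[TriageTrace]]:
    """Run the full algorithm over a cohort and tally the flow nodes."""
    traces = triage_cohort(cohort, events, table)
    total = len(traces)

    graded = {g.value: 0 for g in Grade}
    for t in traces:
        graded[(t.baseline_grade or t.grade).value] += 1

    def baseline_stage(t: TriageTrace, stage: int) -> int | None:
        for r in t.records:
            if r.stage == stage and r.visit_month == 0:
                return r.score
        return None

    exam_applied = sum(1 for t in traces if baseline_stage(t, 2) is not None)
    inv_applied = sum(1 for t in traces if baseline_stage(t, 3) is not None)

    exam_sub = {"below_4": 0, "from_4_to_9": 0, "above_9": 0}
    inv_sub = {"at_most_5": 0, "above_5": 0}
    for t in traces:
        if t.baseline_grade is not Grade.MODERATE:
            continue
        e = baseline_stage(t, 2)
        if e is None:
            continue
        if e < 4:
            exam_sub["below_4"] += 1
        elif e <= 9:
            exam_sub["from_4_to_9"] += 1
            i = baseline_stage(t, 3)
            if i is not None:
                inv_sub["at_most_5" if i <= 5 else "above_5"] += 1
        else:
            exam_sub["above_9"] += 1

    dispositions = {d.value: 0 for d in Disposition}
    for t in traces:
        dispositions[t.disposition.value] += 1

    reassessed = sum(
        1 for t in traces if any(r.visit_month > 0 and r.stage == 1 for r in t.records)
    )
    escalations = sum(
        1
        for t in traces
        if t.baseline_grade is not None and t.grade.rank > t.baseline_grade.rank
    )
    trach = sum(1 for t in traces if Annotation.TRACHEOSTOMY in t.annotations)
    mild_surgical = sum(
        1
        for t in traces
        if t.baseline_grade is Grade.MILD and t.disposition is Disposition.SUPRAGLOTTOPLASTY
    )

    summary = FlowSummary(
        total=total,
        graded=graded,
        graded_pct_1dp={g: _pct(c, total, 1) for g, c in graded.items()},
        graded_pct_2dp={g: _pct(c, total, 2) for g, c in graded.items()},
        exam_stage_applied=exam_applied,
        exam_subgroups_moderate=exam_sub,
        investigation_stage_applied=inv_applied,
        investigation_subgroups_stage3=inv_sub,
        dispositions=dispositions,
        dispositions_pct_1dp={d: _pct(c, total, 1) for d, c in dispositions.items()},
        follow_up_reassessed=reassessed,
        follow_up_escalations=escalations,
        tracheostomies=trach,
        mild_baseline_surgical=mild_surgical,
    )
    return summary, traces


def render_report(summary: FlowSummary, fmt: str = "text") -> str:
    """Render a flow summary as a human-readable table or stable JSON."""
    if fmt == "json":
        return json.dumps(summary.to_dict(), indent=2)
    d = summary.to_dict()
    lines = [
        f"Cohort flow (n = {d['total']})",
        "",
        "Stage 1 - history/symptom score:",
    ]
    for g in ("mild", "moderate", "severe"):
        lines.append(
            f"  {g:<9} {d['graded'][g]:>4}  ({d['graded_pct_1dp'][g]}% / {d['graded_pct_2dp'][g]}%)"
        )
    e = d["exam_subgroups_moderate"]
    lines += [
        "",
        f"Stage 2 - examination score applied to {d['exam_stage_applied']} patients",
        f"  moderate subgroups: <4 -> {e['below_4']}, 4-9 -> {e['from_4_to_9']}, >9 -> {e['above_9']}",
        "",
        f"Stage 3 - investigation score applied to {d['investigation_stage_applied']} patients",
        f"  stage-3 moderate: <=5 -> {d['investigation_subgroups_stage3']['at_most_5']}, "
        f">5 -> {d['investigation_subgroups_stage3']['above_5']}",
        "",
        "Final dispositions:",
    ]
    for k in ("conservative", "watchful_waiting", "supraglottoplasty"):
        lines.append(
            f"  {k:<18} {d['dispositions'][k]:>4}  ({d['dispositions_pct_1dp'][k]}%)"
        )
    lines += [
        "",
        f"Follow-up: {d['follow_up_reassessed']} reassessed, "
        f"{d['follow_up_escalations']} escalated a grade band",
        f"Tracheostomies: {d['tracheostomies']}",
        f"Mild-at-baseline patients reaching surgery: {d['mild_baseline_surgical']}",
    ]
    return "\n".join(lines)
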