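"""Reading and writing cohorts, follow-up events and triage traces.

Cohort files are UTF-8 comma-separated with a header; a missing value is
an empty cell, never zero — an unassessed item is not an asymptomatic
one, and the engine refuses to grade incomplete score parts rather than
imputing.  Patients may be recorded either as pre-coded ordinal points
(one column per item) or as raw measurements (Z-score, collapse
fraction, PAS, ...) which are converted through the clinical mappers;
supplying both for the same item in the same record is an error.
Traces are written as JSON lines, one object per patient, and
round-trip losslessly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import mappers
from .errors import ValidationError
from .score_model import Assessment, ScorePart, ScoreTable, default_table
from .triage import (
    Annotation,
    Disposition,
    FollowUpEvent,
    Grade,
    StageRecord,
    TriageTrace,
)

__all__ = [
    "read_cohort",
    "write_cohort",
    "read_events",
    "load_paper_events",
    "assessments_from_row",
    "write_traces",
    "read_traces",
    "trace_to_dict",
    "trace_from_dict",
]

#: raw-measurement column(s) -> (item id, converter over the row dict)
RAW_COLUMN_MAP = {
    "growth_chart": (("weight_for_length_z",), lambda r: mappers.map_growth_z(r["weight_for_length_z"])),
    "collapse_degree": (("collapse_fraction",), lambda r: mappers.map_collapse(r["collapse_fraction"])),
    "swallowing_fees": (("fees_grade",), lambda r: mappers.map_fees(r["fees_grade"])),
    "developmental": (
        ("gmds_domains_below_normal",),
        lambda r: mappers.map_gmds(r["gmds_domains_below_normal"]),
    ),
    "congenital_anomalies": (("anomaly_count",), lambda r: mappers.map_anomalies(r["anomaly_count"])),
    "echo": (
        ("cardiac_anomaly_present", "pulmonary_pressure_mmHg", "right_heart_failure"),
        lambda r: mappers.map_echo(
            bool(r.get("cardiac_anomaly_present", False)),
            float(r.get("pulmonary_pressure_mmHg", 0.0) or 0.0),
            bool(r.get("right_heart_failure", False)),
        ),
    ),
    "overnight_oximetry": (("o2_nadir_percent",), lambda r: mappers.map_o2_nadir(r["o2_nadir_percent"])),
    "synchronous_airway_lesion": (("sal_count",), lambda r: mappers.map_sal(r["sal_count"])),
    "gerd": (
        ("pas", "reflux_index_percent"),
        lambda r: mappers.gerd_point(r.get("pas"), r.get("reflux_index_percent")),
    ),
}

META_COLUMNS = ("patient_id", "grade", "age_months", "morphology_type")
MORPHOLOGIES = ("I", "II", "III", "MIXED_I_II")


def _point_columns(table: ScoreTable) -> list[str]:
    return [i for part in ScorePart for i in table.item_ids(part)]


def read_cohort(path: str | Path, table: ScoreTable | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV, mapping raw columns to points.

    Returns a DataFrame with one nullable-integer point column per item.
    Validation errors are addressed by row number (1-based, excluding
    the header) and column name; a schema violation never yields a
    partial cohort.
    """
    table = table or default_table()
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"cohort file not found: {path}")
    df = pd.read_csv(path, dtype=object)
    if df.empty:
        warnings.warn(f"{path}: empty cohort file", stacklevel=2)
        return pd.DataFrame(columns=list(META_COLUMNS) + _point_columns(table))

    point_cols = _point_columns(table)
    raw_cols = {c for cols, _ in RAW_COLUMN_MAP.values() for c in cols}
    known = set(META_COLUMNS) | set(point_cols) | raw_cols
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    if "patient_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'patient_id'")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path}: duplicate patient id {dup.iloc[0]!r} at row {int(dup.index[0]) + 1}"
        )

    out_rows = []
    for idx, raw_row in df.iterrows():
        row = {c: (None if pd.isna(v) else v) for c, v in raw_row.items()}
        out = {c: row.get(c) for c in META_COLUMNS}
        if out.get("morphology_type") is not None and out["morphology_type"] not in MORPHOLOGIES:
            raise ValidationError(
                f"{path}: row {idx + 1}, column morphology_type: "
                f"unknown type {out['morphology_type']!r}"
            )
        for part in ScorePart:
            for item in table.items(part):
                cid = item.item_id
                point_given = row.get(cid) is not None
                raw_spec = RAW_COLUMN_MAP.get(cid)
                raw_given = raw_spec is not None and any(
                    row.get(c) is not None for c in raw_spec[0]
                )
                if point_given and raw_given:
                    raise ValidationError(
                        f"{path}: row {idx + 1}: item {cid!r} given both as a point "
                        f"column and as raw measurement(s) {raw_spec[0]}"
                    )
                try:
                    if point_given:
                        out[cid] = item.validate_point(_as_number(row[cid]))
                    elif raw_given:
                        out[cid] = item.validate_point(
                            raw_spec[1]({c: _coerce(row.get(c)) for c in raw_spec[0]})
                        )
                    else:
                        out[cid] = pd.NA
                except ValidationError as err:
                    raise ValidationError(
                        f"{path}: row {idx + 1}, column {cid}: {err}"
                    ) from None
        out_rows.append(out)

    result = pd.DataFrame(out_rows, columns=list(META_COLUMNS) + point_cols)
    result[point_cols] = result[point_cols].astype("Int64")
    if "age_months" in result:
        result["age_months"] = pd.to_numeric(result["age_months"], errors="coerce")
    return result


def _as_number(value):
    try:
        f = float(value)
    except (TypeError, ValueError):
        return value
    return int(f) if f == int(f) else f


def _coerce(value):
    if value is None:
        return None
    if isinstance(value, str):
        low = value.strip().lower()
        if low in ("true", "yes", "1"):
            return True
        if low in ("false", "no", "0"):
            return False
        try:
            return _as_number(value)
        except ValueError:
            return value
    return value


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort CSV (missing values as empty cells)."""
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def assessments_from_row(
    row, table: ScoreTable | None = None
) -> tuple[Assessment, Assessment | None, Assessment | None]:
    """Build (history, exam?, investigation?) assessments from a cohort row.

    A part is returned only when *all* of its items are present; a
    partially filled part raises, since its score would be undefined.
    """
    table = table or default_table()
    parts: list[Assessment | None] = []
    for part in ScorePart:
        ids = table.item_ids(part)
        present = [i for i in ids if i in row and not pd.isna(row[i])]
        if not present:
            parts.append(None)
        elif len(present) < len(ids):
            missing = sorted(set(ids) - set(present))
            raise ValidationError(
                f"patient {row.get('patient_id', '?')}: incomplete {part.value} "
                f"assessment (missing {missing})"
            )
        else:
            parts.append(Assessment(part, {i: int(row[i]) for i in ids}, table))
    history, exam, investigation = parts
    if history is None:
        raise ValidationError(
            f"patient {row.get('patient_id', '?')}: no history assessment"
        )
    return history, exam, investigation


# ---------------------------------------------------------------------------
# events


def read_events(path: str | Path, table: ScoreTable | None = None) -> list[FollowUpEvent]:
    """Read a follow-up events CSV into :class:`FollowUpEvent` objects."""
    table = table or default_table()
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"events file not found: {path}")
    df = pd.read_csv(path, dtype=object)
    events = []
    for idx, raw_row in df.iterrows():
        row = {c: (None if pd.isna(v) else v) for c, v in raw_row.items()}
        try:
            parts: dict[str, Assessment | None] = {}
            for part in (ScorePart.HISTORY, ScorePart.EXAM):
                ids = table.item_ids(part)
                present = [i for i in ids if row.get(i) is not None]
                if present and len(present) < len(ids):
                    raise ValidationError(
                        f"incomplete {part.value} assessment "
                        f"(missing {sorted(set(ids) - set(present))})"
                    )
                parts[part.value] = (
                    Assessment(part, {i: int(float(row[i])) for i in ids}, table)
                    if present
                    else None
                )
            events.append(
                FollowUpEvent(
                    patient_id=str(row["patient_id"]),
                    visit_month=int(float(row["visit_month"])),
                    event_type=str(row.get("event_type") or "reassessment"),
                    history=parts["history"],
                    exam=parts["exam"],
                    note=str(row.get("note") or ""),
                )
            )
        except (ValidationError, KeyError, TypeError, ValueError) as err:
            raise ValidationError(f"{path}: row {idx + 1}: {err}") from None
    return events


def load_paper_events(table: ScoreTable | None = None) -> list[FollowUpEvent]:
    """The packaged scripted-events fixture transcribing the study narrative.

    Five mild patients escalate into the moderate band but stay
    conservative (exam < 4); one watchful-waiting patient deteriorates
    to the severe band and undergoes surgery; one surgical patient has a
    postoperative airway compromise; three synchronous-airway-lesion
    patients need tracheostomy alongside supraglottoplasty.  Ids rely on
    the canonical ordering of the replica cohort.
    """
    from importlib import resources

    with resources.as_file(
        resources.files("lmscore.data").joinpath("paper_events.csv")
    ) as p:
        return read_events(p, table)


# ---------------------------------------------------------------------------
# traces


def trace_to_dict(trace: TriageTrace) -> dict:
    return {
        "patient_id": trace.patient_id,
        "grade": trace.grade.value,
        "baseline_grade": trace.baseline_grade.value if trace.baseline_grade else None,
        "disposition": trace.disposition.value,
        "annotations": sorted(a.value for a in trace.annotations),
        "records": [
            {
                "stage": r.stage,
                "score": r.score,
                "rule": r.rule,
                "route": r.route,
                "visit_month": r.visit_month,
            }
            for r in trace.records
        ],
        "follow_up_months": list(trace.follow_up_months),
        "horizon_months": trace.horizon_months,
    }


def trace_from_dict(d: dict) -> TriageTrace:
    try:
        return TriageTrace(
            patient_id=d["patient_id"],
            grade=Grade(d["grade"]),
            baseline_grade=Grade(d["baseline_grade"]) if d.get("baseline_grade") else None,
            disposition=Disposition(d["disposition"]),
            annotations=frozenset(Annotation(a) for a in d.get("annotations", [])),
            records=tuple(
                StageRecord(
                    stage=int(r["stage"]),
                    score=int(r["score"]),
                    rule=r["rule"],
                    route=r["route"],
                    visit_month=int(r.get("visit_month", 0)),
                )
                for r in d.get("records", [])
            ),
            follow_up_months=tuple(d.get("follow_up_months", [])),
            horizon_months=int(d.get("horizon_months", 6)),
        )
    except (KeyError, ValueError) as err:
        raise ValidationError(f"malformed trace object: {err}") from None


def write_traces(traces: Iterable[TriageTrace], path: str | Path) -> Path:
    """Write traces as JSON lines (one object per patient)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for trace in traces:
            fh.write(json.dumps(trace_to_dict(trace), sort_keys=True) + "\n")
    return path


def read_traces(path: str | Path) -> list[TriageTrace]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"traces file not found: {path}")
    traces = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                traces.append(trace_from_dict(json.loads(line)))
            except json.JSONDecodeError as err:
                raise ValidationError(f"{path}: line {lineno}: invalid JSON ({err})") from None
    return traces
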