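"""Synthetic cohorts consistent with published per-grade marginal tables.

No patient-level laryngomalacia dataset is public: the study that
motivates this package published only, for each severity grade, the
count of patients at each point value of each item (marginal tables),
plus the grade's score band and the sizes of the management subgroups.
This module reconstructs patient-level cohorts consistent with those
constraints.

Two modes:

* **replica** — exact reconstruction: for every grade and score part,
  each item's published point multiset is distributed over the patients
  so that the per-item counts equal the marginals *exactly* (swaps
  preserve counts, so exactness holds by construction) and every
  patient's part score falls in the required band.  The assignment is a
  seeded randomized search (greedy band-targeted initialisation, then
  local-search repair by pairwise swaps, with bounded restarts); it
  fails loudly if no assignment is found.  The joint distribution
  across items is *not* identified by the marginals — the replica is
  one feasible cohort, not the real one.

* **parametric** — cohorts of arbitrary size sampled item-wise from
  per-grade multinomials (defaulting to the published proportions),
  rejection-sampled into the grade's history-score band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleError, ValidationError
from .score_model import ScorePart, ScoreTable, default_config, default_table
from .triage import Grade

__all__ = [
    "MarginalTable",
    "CohortSpec",
    "MarginalReport",
    "load_paper_marginals",
    "solve_assignment",
    "assignment_exists",
    "reconstruct_paper_cohort",
    "generate_cohort",
    "verify_marginals",
    "PAPER_GROUP_SIZES",
    "MODERATE_EXAM_SPLIT",
    "STAGE3_SPLIT",
    "MORPHOLOGY_COUNTS",
]

#: published cohort composition: grade sizes, moderate examination-band
#: split (<4 / 4-9 / >9), stage-3 investigation split (<=5 / >5), and
#: morphology-type counts (I / II / III / mixed I+II).
PAPER_GROUP_SIZES = {"mild": 44, "moderate": 48, "severe": 20}
MODERATE_EXAM_SPLIT = (13, 22, 13)
STAGE3_SPLIT = (11, 11)
MORPHOLOGY_COUNTS = {"I": 21, "II": 61, "III": 6, "MIXED_I_II": 24}

MORPHOLOGY_TYPES = tuple(MORPHOLOGY_COUNTS)
AGE_MEAN, AGE_SD = 4.3, 2.2


@dataclass(frozen=True)
class MarginalTable:
    """Per-point patient counts for every item of one part in one group."""

    part: ScorePart
    group: str
    counts: Mapping[str, Mapping[int, int]]
    group_total: int = field(default=0)

    def __post_init__(self) -> None:
        totals = {item: sum(pts.values()) for item, pts in self.counts.items()}
        expected = self.group_total or next(iter(totals.values()), 0)
        object.__setattr__(self, "group_total", expected)
        for item, total in totals.items():
            if total != expected:
                raise ValidationError(
                    f"{self.part.value}/{self.group}/{item}: counts sum to {total}, "
                    f"expected group total {expected}"
                )
        for item, pts in self.counts.items():
            for point, count in pts.items():
                if count < 0:
                    raise ValidationError(
                        f"{self.part.value}/{self.group}/{item}: negative count at point {point}"
                    )

    def multisets(self) -> dict[str, dict[int, int]]:
        return {item: dict(pts) for item, pts in self.counts.items()}

    @property
    def total_points(self) -> int:
        return sum(p * c for pts in self.counts.values() for p, c in pts.items())


def load_paper_marginals(
    table: ScoreTable | None = None,
) -> dict[tuple[ScorePart, str], MarginalTable]:
    """Load the packaged marginal tables (per-grade item-point counts)."""
    table = table or default_table()
    text = resources.files("lmscore.data").joinpath("marginals.csv").read_text()
    df = pd.read_csv(StringIO(text))
    out: dict[tuple[ScorePart, str], MarginalTable] = {}
    for (part_name, group), sub in df.groupby(["part", "group"], sort=False):
        part = ScorePart(part_name)
        counts: dict[str, dict[int, int]] = {}
        for _, row in sub.iterrows():
            item = table.item(part, row["item_id"])  # validates the id
            point = int(row["point"])
            if point not in item.allowed_points:
                raise ValidationError(
                    f"marginals {part.value}/{group}/{row['item_id']}: "
                    f"point {point} not allowed"
                )
            counts.setdefault(row["item_id"], {})[point] = int(row["count"])
        expected = PAPER_GROUP_SIZES.get(group, 0) if part is ScorePart.HISTORY else 0
        out[(part, group)] = MarginalTable(part, str(group), counts, expected)
    return out


# ---------------------------------------------------------------------------
# constrained assignment solver


def solve_assignment(
    counts: Mapping[str, Mapping[int, int]],
    bands: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    max_restarts: int = 40,
    max_iters: int = 60_000,
) -> list[dict[str, int]]:
    """Distribute each item's point multiset over slots within score bands.

    ``counts[item][point]`` gives how many slots must receive ``point``
    for ``item``; ``bands[i]`` is the inclusive (lo, hi) band required
    of slot *i*'s total.  Returns one point dict per slot whose per-item
    value counts equal ``counts`` exactly.  Raises
    :class:`InfeasibleError` after bounded restarts.
    """
    n = len(bands)
    items = list(counts)
    for item, pts in counts.items():
        total = sum(pts.values())
        if total != n:
            raise ValidationError(
                f"item {item!r}: counts sum to {total}, expected {n} slots"
            )
    lo = np.array([b[0] for b in bands])
    hi = np.array([b[1] for b in bands])
    if np.any(lo > hi):
        raise ValidationError("band with lo > hi")
    total_pts = sum(p * c for pts in counts.values() for p, c in pts.items())
    if not int(lo.sum()) <= total_pts <= int(hi.sum()):
        raise InfeasibleError(
            f"total points {total_pts} outside aggregate band "
            f"[{int(lo.sum())}, {int(hi.sum())}]"
        )

    target = (lo + hi) / 2.0
    values = {
        item: np.repeat(
            [p for p in sorted(pts)], [pts[p] for p in sorted(pts)]
        )
        for item, pts in counts.items()
    }

    for _ in range(max_restarts):
        assign = _greedy_init(items, values, target, n, rng)
        if _repair(assign, items, lo, hi, n, rng, max_iters):
            return [{item: int(assign[item][i]) for item in items} for i in range(n)]
    raise InfeasibleError(
        f"no assignment satisfying the marginals and bands found for "
        f"{n} slots after {max_restarts} restarts"
    )


def _greedy_init(items, values, target, n, rng) -> dict[str, np.ndarray]:
    """Hand out each item's values, largest first to the neediest slots."""
    assign: dict[str, np.ndarray] = {}
    sums = np.zeros(n)
    order = list(items)
    rng.shuffle(order)
    for item in order:
        vals = np.sort(values[item])[::-1]
        deficit = target - sums + rng.uniform(0, 0.25, n)  # random tie-break
        slot_order = np.argsort(-deficit, kind="stable")
        arr = np.empty(n, dtype=int)
        arr[slot_order] = vals
        assign[item] = arr
        sums += arr
    return assign


def _repair(assign, items, lo, hi, n, rng, max_iters) -> bool:
    """Pairwise-swap local search driving band violations to zero."""
    sums = np.zeros(n, dtype=int)
    for item in items:
        sums += assign[item]

    def viol(s):
        return np.maximum(lo - s, 0) + np.maximum(s - hi, 0)

    v = viol(sums)
    total = int(v.sum())
    stall = 0
    for _ in range(max_iters):
        if total == 0:
            return True
        if stall > 4000:
            return False
        bad = np.flatnonzero(v > 0)
        p = int(rng.choice(bad))
        need_up = sums[p] < lo[p]
        improved = False
        for item in rng.permutation(items):
            vp = assign[item][p]
            col = assign[item]
            if need_up:
                cands = np.flatnonzero(col > vp)
            else:
                cands = np.flatnonzero(col < vp)
            if cands.size == 0:
                continue
            q = int(rng.choice(cands))
            d = int(col[q] - vp)
            new_p, new_q = sums[p] + d, sums[q] - d
            delta = (
                max(lo[p] - new_p, 0) + max(new_p - hi[p], 0) - v[p]
                + max(lo[q] - new_q, 0) + max(new_q - hi[q], 0) - v[q]
            )
            if delta < 0 or (delta == 0 and rng.random() < 0.25):
                col[p], col[q] = col[q], vp
                sums[p], sums[q] = new_p, new_q
                v[p] = max(lo[p] - new_p, 0) + max(new_p - hi[p], 0)
                v[q] = max(lo[q] - new_q, 0) + max(new_q - hi[q], 0)
                total += delta
                improved = delta < 0
                break
        stall = 0 if improved else stall + 1
    return total == 0


def assignment_exists(
    counts: Mapping[str, Mapping[int, int]], bands: Sequence[tuple[int, int]]
) -> bool:
    """Exhaustive feasibility oracle for small instances (<= ~6 slots).

    Depth-first search over slots, trying every per-item value
    combination from the remaining multisets whose sum lies in the
    slot's band.  Intended as an independent check of the randomized
    solver on tiny instances; cost grows combinatorially with slots.
    """
    items = list(counts)
    remaining = {item: dict(pts) for item, pts in counts.items()}

    def options(slot: int):
        lo, hi = bands[slot]
        avail = [sorted(p for p, c in remaining[item].items() if c > 0) for item in items]
        for combo in itertools.product(*avail):
            if lo <= sum(combo) <= hi:
                yield combo

    def dfs(slot: int) -> bool:
        if slot == len(bands):
            return True
        for combo in options(slot):
            for item, p in zip(items, combo):
                remaining[item][p] -= 1
            if dfs(slot + 1):
                return True
            for item, p in zip(items, combo):
                remaining[item][p] += 1
        return False

    return dfs(0)


# ---------------------------------------------------------------------------
# replica reconstruction


def _part_columns(table: ScoreTable) -> dict[ScorePart, list[str]]:
    return {part: table.item_ids(part) for part in ScorePart}


def _bands_from_config() -> dict:
    return default_config()["thresholds"]


def reconstruct_paper_cohort(
    seed: int = 0,
    marginals: Mapping[tuple[ScorePart, str], MarginalTable] | None = None,
    table: ScoreTable | None = None,
) -> pd.DataFrame:
    """Reconstruct a 112-patient cohort exactly matching the marginals.

    Patient ids are canonical: mild patients (M001-M044) sorted by
    history score; moderate patients (D001-D048) ordered by management
    subgroup — exam < 4 (D001-D013), watchful waiting (D014-D024),
    stage-3 surgical (D025-D035), exam > 9 (D036-D048); severe patients
    (S001-S020) sorted by synchronous-airway-lesion point descending.
    This makes scripted event fixtures referring to ids valid for every
    seed.
    """
    table = table or default_table()
    marginals = marginals if marginals is not None else load_paper_marginals(table)
    rng = np.random.default_rng(seed)
    th = _bands_from_config()
    g_bands = th["grade_bands"]
    e_bands = th["exam_bands"]
    inv_max = th["investigation_watchful_max"]
    cols = _part_columns(table)

    def solve(part: ScorePart, group: str, bands):
        key = (part, group)
        if key not in marginals:
            raise ValidationError(f"missing marginal table for {part.value}/{group}")
        return solve_assignment(marginals[key].multisets(), bands, rng)

    # history: every patient's score sits in the grade band
    hist = {
        g: solve(ScorePart.HISTORY, g, [tuple(g_bands[g])] * PAPER_GROUP_SIZES[g])
        for g in ("mild", "moderate", "severe")
    }

    # exam: moderate patients split 13 / 22 / 13 across the routing bands,
    # severe patients are unconstrained (preoperative baseline only)
    n_low, n_mid, n_high = MODERATE_EXAM_SPLIT
    exam_bands = (
        [tuple(e_bands["conservative"])] * n_low
        + [tuple(e_bands["stage3"])] * n_mid
        + [tuple(e_bands["surgery"])] * n_high
    )
    exam_mod = solve(ScorePart.EXAM, "moderate", exam_bands)
    exam_sev = solve(ScorePart.EXAM, "severe", [(0, 13)] * PAPER_GROUP_SIZES["severe"])

    # investigation: of the 22 stage-3 moderate patients, 11 fall at or
    # below the watchful-waiting cut and 11 above; the 13 exam > 9
    # patients carry unconstrained baselines
    n_watch, n_surg = STAGE3_SPLIT
    inv_bands = (
        [(0, inv_max)] * n_watch + [(inv_max + 1, 10)] * n_surg + [(0, 10)] * n_high
    )
    inv_mod = solve(ScorePart.INVESTIGATION, "moderate", inv_bands)
    inv_sev = solve(
        ScorePart.INVESTIGATION, "severe", [(0, 10)] * PAPER_GROUP_SIZES["severe"]
    )

    def score(vec: Mapping[str, int]) -> int:
        return sum(vec.values())

    patients: list[dict] = []

    # mild: history only
    mild_hist = sorted(hist["mild"], key=lambda v: (score(v), tuple(v.values())))
    for vec in mild_hist:
        patients.append({"grade": "mild", "history": vec, "exam": None, "inv": None})

    # moderate: pair exam subgroups with their investigation vectors
    mod_hist = list(hist["moderate"])
    rng.shuffle(mod_hist)
    exam_low = exam_mod[:n_low]
    exam_mid = exam_mod[n_low : n_low + n_mid]
    exam_high = exam_mod[n_low + n_mid :]
    inv_mid = inv_mod[: n_watch + n_surg]
    inv_high = inv_mod[n_watch + n_surg :]
    rng.shuffle(exam_mid)  # decouple exam level from investigation band
    rng.shuffle(inv_high)

    mod_patients = []
    for e in exam_low:
        mod_patients.append({"subgroup": 0, "exam": e, "inv": None})
    for e, i in zip(exam_mid, inv_mid):
        sub = 1 if score(i) <= inv_max else 2
        mod_patients.append({"subgroup": sub, "exam": e, "inv": i})
    for e, i in zip(exam_high, inv_high):
        mod_patients.append({"subgroup": 3, "exam": e, "inv": i})
    mod_patients.sort(
        key=lambda p: (
            p["subgroup"],
            score(p["exam"]),
            score(p["inv"]) if p["inv"] else -1,
            tuple(p["exam"].values()),
            tuple(p["inv"].values()) if p["inv"] else (),
        )
    )
    for p, h in zip(mod_patients, mod_hist):
        patients.append({"grade": "moderate", "history": h, "exam": p["exam"], "inv": p["inv"]})

    # severe: sort by SAL point descending so scripted lesion events can
    # target ids with guaranteed lesion counts
    sev = [
        {"history": h, "exam": e, "inv": i}
        for h, e, i in zip(hist["severe"], exam_sev, inv_sev)
    ]
    sev.sort(
        key=lambda p: (
            -p["inv"]["synchronous_airway_lesion"],
            -score(p["inv"]),
            tuple(p["inv"].values()),
            tuple(p["exam"].values()),
            tuple(p["history"].values()),
        )
    )
    for p in sev:
        patients.append({"grade": "severe", **p})

    prefixes = {"mild": "M", "moderate": "D", "severe": "S"}
    counters = {g: 0 for g in prefixes}
    morph = np.repeat(MORPHOLOGY_TYPES, [MORPHOLOGY_COUNTS[t] for t in MORPHOLOGY_TYPES])
    rng.shuffle(morph)
    ages = np.clip(rng.normal(AGE_MEAN, AGE_SD, len(patients)), 0.5, 12.0).round(1)

    rows = []
    for k, p in enumerate(patients):
        counters[p["grade"]] += 1
        row = {
            "patient_id": f"{prefixes[p['grade']]}{counters[p['grade']]:03d}",
            "grade": p["grade"],
            "age_months": ages[k],
            "morphology_type": morph[k],
        }
        row.update(p["history"])
        for part, vec in ((ScorePart.EXAM, p["exam"]), (ScorePart.INVESTIGATION, p["inv"])):
            for item in cols[part]:
                row[item] = vec[item] if vec is not None else pd.NA
        rows.append(row)

    df = pd.DataFrame(rows)
    point_cols = cols[ScorePart.HISTORY] + cols[ScorePart.EXAM] + cols[ScorePart.INVESTIGATION]
    df[point_cols] = df[point_cols].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# parametric generation


@dataclass(frozen=True)
class CohortSpec:
    """Specification for a parametric synthetic cohort.

    ``n_per_grade`` defaults to the published 44/48/20; item point
    probabilities default to the published per-grade proportions.
    History vectors are rejection-sampled into the grade band.
    """

    n_per_grade: Mapping[str, int] = field(
        default_factory=lambda: dict(PAPER_GROUP_SIZES)
    )
    probabilities: Mapping[tuple[ScorePart, str], Mapping[str, Mapping[int, float]]] | None = None
    seed: int = 0
    max_rejections: int = 100_000

    def __post_init__(self) -> None:
        for g, n in self.n_per_grade.items():
            if g not in PAPER_GROUP_SIZES:
                raise ValidationError(f"unknown grade {g!r} in cohort spec")
            if n < 0:
                raise ValidationError(f"negative cohort size for grade {g!r}")
        if self.probabilities is not None:
            for key, items in self.probabilities.items():
                for item, pp in items.items():
                    total = sum(pp.values())
                    if abs(total - 1.0) > 1e-9:
                        raise ValidationError(
                            f"probabilities for {key}/{item} sum to {total}, not 1"
                        )


def _default_probabilities(table: ScoreTable):
    probs: dict[tuple[ScorePart, str], dict[str, dict[int, float]]] = {}
    for key, mt in load_paper_marginals(table).items():
        probs[key] = {
            item: {p: c / mt.group_total for p, c in pts.items()}
            for item, pts in mt.counts.items()
        }
    return probs


def generate_cohort(spec: CohortSpec, table: ScoreTable | None = None) -> pd.DataFrame:
    """Sample a parametric cohort; deterministic given the spec's seed."""
    table = table or default_table()
    rng = np.random.default_rng(spec.seed)
    probs = spec.probabilities or _default_probabilities(table)
    g_bands = _bands_from_config()["grade_bands"]
    cols = _part_columns(table)

    def sample_vector(part: ScorePart, grade: str) -> dict[str, int]:
        item_probs = probs[(part, grade)]
        return {
            item: int(rng.choice(sorted(pp), p=[pp[k] for k in sorted(pp)]))
            for item, pp in item_probs.items()
        }

    rows = []
    prefixes = {"mild": "M", "moderate": "D", "severe": "S"}
    for grade in ("mild", "moderate", "severe"):
        n = spec.n_per_grade.get(grade, 0)
        lo, hi = g_bands[grade]
        for k in range(n):
            for attempt in range(spec.max_rejections):
                h = sample_vector(ScorePart.HISTORY, grade)
                if lo <= sum(h.values()) <= hi:
                    break
            else:
                raise InfeasibleError(
                    f"could not sample a {grade} history vector in band "
                    f"[{lo}, {hi}] after {spec.max_rejections} rejections"
                )
            row = {
                "patient_id": f"{prefixes[grade]}{k + 1:03d}",
                "grade": grade,
                "age_months": round(float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 0.5, 12.0)), 1),
                "morphology_type": str(
                    rng.choice(
                        MORPHOLOGY_TYPES,
                        p=[MORPHOLOGY_COUNTS[t] / 112 for t in MORPHOLOGY_TYPES],
                    )
                ),
            }
            row.update(h)
            if grade == "mild":
                for item in cols[ScorePart.EXAM] + cols[ScorePart.INVESTIGATION]:
                    row[item] = pd.NA
            else:
                row.update(sample_vector(ScorePart.EXAM, grade))
                row.update(sample_vector(ScorePart.INVESTIGATION, grade))
            rows.append(row)

    df = pd.DataFrame(rows)
    point_cols = cols[ScorePart.HISTORY] + cols[ScorePart.EXAM] + cols[ScorePart.INVESTIGATION]
    df[point_cols] = df[point_cols].astype("Int64")
    return df


# ---------------------------------------------------------------------------
# verification


@dataclass(frozen=True)
class MarginalReport:
    """Outcome of an exact cohort-vs-marginals comparison."""

    passed: bool
    diffs: tuple[tuple[str, str, str, int, int, int], ...]  # part, group, item, point, want, got

    def __str__(self) -> str:
        if self.passed:
            return "marginals: PASS (exact match)"
        lines = ["marginals: FAIL"]
        for part, group, item, point, want, got in self.diffs:
            lines.append(f"  {part}/{group}/{item} point {point}: expected {want}, got {got}")
        return "\n".join(lines)


def verify_marginals(
    cohort: pd.DataFrame,
    marginals: Mapping[tuple[ScorePart, str], MarginalTable] | None = None,
    table: ScoreTable | None = None,
) -> MarginalReport:
    """Exact per-(group, item, point) count comparison of a cohort."""
    table = table or default_table()
    marginals = marginals if marginals is not None else load_paper_marginals(table)
    diffs = []
    for (part, group), mt in marginals.items():
        if "grade" in cohort.columns:
            sub = cohort[cohort["grade"] == group]
        else:
            sub = cohort
        for item, pts in mt.counts.items():
            if item in sub.columns:
                observed = sub[item].dropna().astype(int).value_counts().to_dict()
            else:
                observed = {}
            for point, want in pts.items():
                got = int(observed.get(point, 0))
                if got != want:
                    diffs.append((part.value, group, item, point, want, got))
    return MarginalReport(passed=not diffs, diffs=tuple(diffs))
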