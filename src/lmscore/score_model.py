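"""The three-part laryngomalacia score table and composite-score arithmetic.

The severity score has three parts — a history/symptom score (7 items,
0-15 points), an examination score (6 items, 0-13) and an investigation
score (4 items, 0-10).  Each item is an ordinal checkpoint worth 0-3
points (3 = most severe); a part score is the plain sum of its item
points.  The item definitions are data, not code: they are loaded from a
versioned YAML config so that cut-offs and labels can be refined without
touching the engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

import yaml

from .errors import ValidationError

__all__ = [
    "ScorePart",
    "ItemDefinition",
    "ScoreTable",
    "Assessment",
    "load_score_table",
    "default_config",
    "compute_score",
    "max_score",
    "enumerate_assessments",
]


class ScorePart(str, Enum):
    """Which of the three parts of the scoring system an item belongs to."""

    HISTORY = "history"
    EXAM = "exam"
    INVESTIGATION = "investigation"


@dataclass(frozen=True)
class ItemDefinition:
    """One ordinal checklist item: its part, allowed points and labels."""

    item_id: str
    score_part: ScorePart
    allowed_points: frozenset[int]
    labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.allowed_points <= {0, 1, 2, 3}:
            raise ValidationError(
                f"item {self.item_id!r}: allowed points {sorted(self.allowed_points)} "
                "outside {0,1,2,3}"
            )
        if 0 not in self.allowed_points:
            raise ValidationError(f"item {self.item_id!r}: 0 must be an allowed point")

    @property
    def max_point(self) -> int:
        return max(self.allowed_points)

    def validate_point(self, value: object) -> int:
        """Coerce and check one recorded point value for this item."""
        if value is None:
            raise ValidationError(f"item {self.item_id!r}: missing point value")
        try:
            point = int(value)
        except (TypeError, ValueError):
            raise ValidationError(
                f"item {self.item_id!r}: point value {value!r} is not an integer"
            ) from None
        if isinstance(value, float) and value != point:
            raise ValidationError(
                f"item {self.item_id!r}: point value {value!r} is not an integer"
            )
        if point not in self.allowed_points:
            raise ValidationError(
                f"item {self.item_id!r}: point {point} not in allowed set "
                f"{sorted(self.allowed_points)}"
            )
        return point


class ScoreTable:
    """An ordered collection of item definitions grouped by score part."""

    def __init__(self, items: list[ItemDefinition], version: int = 1):
        self.version = version
        self._items: dict[ScorePart, dict[str, ItemDefinition]] = {
            part: {} for part in ScorePart
        }
        for item in items:
            part_items = self._items[item.score_part]
            if item.item_id in part_items:
                raise ValidationError(f"duplicate item id {item.item_id!r}")
            part_items[item.item_id] = item

    def items(self, part: ScorePart) -> list[ItemDefinition]:
        return list(self._items[self._coerce_part(part)].values())

    def item_ids(self, part: ScorePart) -> list[str]:
        return list(self._items[self._coerce_part(part)])

    def item(self, part: ScorePart, item_id: str) -> ItemDefinition:
        try:
            return self._items[self._coerce_part(part)][item_id]
        except KeyError:
            raise ValidationError(f"unknown item {item_id!r} in part {part}") from None

    @staticmethod
    def _coerce_part(part: object) -> ScorePart:
        try:
            return ScorePart(part)
        except ValueError:
            raise ValidationError(f"unknown score part {part!r}") from None


@dataclass(frozen=True)
class Assessment:
    """A patient's complete item-point vector for one score part.

    Points are validated eagerly against the score table: every item of
    the part must be present with an allowed value.  A score is undefined
    on partial data — the constructor refuses rather than imputing.
    """

    part: ScorePart
    points: Mapping[str, int]
    table: ScoreTable = field(compare=False, repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        table = self.table or default_table()
        object.__setattr__(self, "table", table)
        validated: dict[str, int] = {}
        for item in table.items(self.part):
            if item.item_id not in self.points:
                raise ValidationError(
                    f"{self.part.value} assessment: missing item {item.item_id!r}"
                )
            validated[item.item_id] = item.validate_point(self.points[item.item_id])
        extra = set(self.points) - set(validated)
        if extra:
            raise ValidationError(
                f"{self.part.value} assessment: unknown items {sorted(extra)}"
            )
        object.__setattr__(self, "points", validated)

    @property
    def score(self) -> int:
        return sum(self.points.values())

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.points[i] for i in self.table.item_ids(self.part))


def history_assessment(points: Mapping[str, int], table: ScoreTable | None = None) -> Assessment:
    return Assessment(ScorePart.HISTORY, points, table)


def exam_assessment(points: Mapping[str, int], table: ScoreTable | None = None) -> Assessment:
    return Assessment(ScorePart.EXAM, points, table)


def investigation_assessment(points: Mapping[str, int], table: ScoreTable | None = None) -> Assessment:
    return Assessment(ScorePart.INVESTIGATION, points, table)


def default_config() -> dict:
    """Parsed contents of the packaged config (score table + thresholds)."""
    return _load_default_config()


@lru_cache(maxsize=1)
def _load_default_config() -> dict:
    text = resources.files("lmscore.data").joinpath("config.yaml").read_text()
    return yaml.safe_load(text)


def load_score_table(config: Mapping | None = None) -> ScoreTable:
    """Build a :class:`ScoreTable` from a parsed config mapping.

    With no argument, loads the packaged default table (history 0-15,
    exam 0-13, investigation 0-10).
    """
    if config is None:
        return default_table()
    return _table_from_config(config)


@lru_cache(maxsize=1)
def default_table() -> ScoreTable:
    return _table_from_config(default_config())


def _table_from_config(config: Mapping) -> ScoreTable:
    try:
        table_cfg = config["score_table"]
    except (KeyError, TypeError):
        raise ValidationError("config missing 'score_table' section") from None
    items = []
    for part_name, part_items in table_cfg.items():
        part = ScoreTable._coerce_part(part_name)
        for item_id, spec in part_items.items():
            items.append(
                ItemDefinition(
                    item_id=item_id,
                    score_part=part,
                    allowed_points=frozenset(spec["points"]),
                    labels={int(k): v for k, v in spec.get("labels", {}).items()},
                )
            )
    return ScoreTable(items, version=config.get("version", 1))


def compute_score(assessment: Assessment) -> int:
    """Composite score: exact integer sum of the validated item points."""
    return assessment.score


def max_score(part: ScorePart, table: ScoreTable | None = None) -> int:
    """Maximum attainable score for a part (sum of per-item maxima)."""
    table = table or default_table()
    return sum(item.max_point for item in table.items(part))


def enumerate_assessments(
    part: ScorePart, table: ScoreTable | None = None
) -> Iterator[Assessment]:
    """Yield every valid item vector for a part, in lexicographic order.

    Used as a brute-force oracle: the history part has 1458 vectors, the
    examination part 972 and the investigation part 144.
    """
    table = table or default_table()
    items = table.items(part)
    ids = [i.item_id for i in items]
    for combo in itertools.product(*(sorted(i.allowed_points) for i in items)):
        yield Assessment(part, dict(zip(ids, combo)), table)
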