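"""Domain types and I/O for gross-motor-task component ratings.

A gross motor task is characterised by three ordinal component measures
hypothesised to drive its difficulty:

* **body position** (1–12): how far the head and centre of mass are from
  the ground / how small the base of support is (supine ... one-foot
  standing ... airborne);
* **movement** (1–22): the developmental milestone the task demands
  (no movement ... rolling ... crawling ... walking ... hopping);
* **support** (1–5): how much external support the task allows (full
  proximal and head support ... no support).

Ratings are plain integer codes; the category label text is carried as
metadata only (``BODY_POSITION_LABELS`` etc.), because the downstream
regression consumes the numeric codes.

The 66-item GMFM-66 rating table and the published GM-unit reference
table ship as bundled CSV fixtures, accessible through
:func:`bundled_gmfm_ratings` and :func:`bundled_reference_table`.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

__all__ = [
    "ValidationError",
    "ParseError",
    "ComponentRatings",
    "GrossMotorTask",
    "TaskTable",
    "ReferenceRow",
    "RATING_RANGES",
    "BODY_POSITION_LABELS",
    "MOVEMENT_LABELS",
    "SUPPORT_LABELS",
    "validate_ratings",
    "read_task_table",
    "write_task_table",
    "bundled_gmfm_ratings",
    "bundled_reference_table",
]


class ValidationError(ValueError):
    """A component rating (or task) violates the rating-schema constraints."""


class ParseError(ValueError):
    """A task-rating file could not be parsed into a valid table."""


#: Legal inclusive range of each component rating.
RATING_RANGES: dict[str, tuple[int, int]] = {
    "body_position": (1, 12),
    "movement": (1, 22),
    "support": (1, 5),
}

#: Category labels for the body-position component (metadata only).
BODY_POSITION_LABELS: dict[int, str] = {
    1: "Supine",
    2: "Prone",
    3: "Sitting",
    4: "Quadruped",
    5: "3-Point",
    6: "Tall Kneel",
    7: "Half Kneel",
    8: "Standing",
    9: "Standing - Staggered (feet apart)",
    10: "Standing - Tandem",
    11: "Standing on one foot",
    12: "Period without contact with the ground",
}

#: Category labels for the movement component (metadata only).
MOVEMENT_LABELS: dict[int, str] = {
    1: "No movement",
    2: "Controlled head movement",
    3: "Rolling",
    4: "Lying to Sitting",
    5: "Sitting to Quadruped",
    6: "4-Point to 3-Point",
    7: "Crawling (reciprocal)",
    8: "Quadruped to Kneel",
    9: "Pull to Stand",
    10: "Sit to Stand",
    11: "Stand to Sit",
    12: "Kneel to Stand",
    13: "Cruising",
    14: "Walking",
    15: "Squatting",
    16: "Walking with challenge",
    17: "Walking up stairs",
    18: "Walking down stairs",
    19: "Kicking",
    20: "Running",
    21: "Jumping",
    22: "Hopping on one foot",
}

#: Category labels for the support component (metadata only).
SUPPORT_LABELS: dict[int, str] = {
    1: "Full proximal and head support",
    2: "Full proximal support without head support",
    3: "Two hand support without proximal support",
    4: "One hand support without proximal support",
    5: "No support",
}


@dataclass(frozen=True)
class ComponentRatings:
    """The ordinal (body position, movement, support) triple for one task."""

    body_position: int
    movement: int
    support: int

    def __post_init__(self) -> None:
        for name in ("body_position", "movement", "support"):
            value = getattr(self, name)
            lo, hi = RATING_RANGES[name]
            if isinstance(value, bool) or not isinstance(value, int):
                raise ValidationError(
                    f"{name} rating must be an integer in [{lo}, {hi}], "
                    f"got {value!r}"
                )
            if not lo <= value <= hi:
                raise ValidationError(
                    f"{name} rating {value} outside legal range [{lo}, {hi}]"
                )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.body_position, self.movement, self.support)


@dataclass(frozen=True)
class GrossMotorTask:
    """One gross motor task: identifier, free-text name, component ratings.

    ``item_name`` is display metadata and is never used as a join key
    (spellings of the same item differ across published tables).
    """

    item_number: int
    item_name: str
    ratings: ComponentRatings

    def __post_init__(self) -> None:
        if isinstance(self.item_number, bool) or not isinstance(self.item_number, int):
            raise ValidationError(f"item_number must be an integer, got {self.item_number!r}")
        if self.item_number <= 0:
            raise ValidationError(f"item_number must be positive, got {self.item_number}")


@dataclass(frozen=True)
class TaskTable:
    """An ordered, duplicate-free, non-empty collection of tasks."""

    tasks: tuple[GrossMotorTask, ...]

    def __post_init__(self) -> None:
        if not self.tasks:
            raise ValidationError("task table contains no tasks")
        seen: set[int] = set()
        for task in self.tasks:
            if task.item_number in seen:
                raise ValidationError(f"duplicate item_number {task.item_number}")
            seen.add(task.item_number)

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self) -> Iterator[GrossMotorTask]:
        return iter(self.tasks)

    def __getitem__(self, item_number: int) -> GrossMotorTask:
        for task in self.tasks:
            if task.item_number == item_number:
                return task
        raise KeyError(item_number)

    @property
    def item_numbers(self) -> tuple[int, ...]:
        return tuple(t.item_number for t in self.tasks)

    def ratings_matrix(self) -> list[list[int]]:
        """Rows of (body_position, movement, support) in table order."""
        return [list(t.ratings.as_tuple()) for t in self.tasks]


@dataclass(frozen=True)
class ReferenceRow:
    """One row of the published GM-unit reference table."""

    item_number: int
    item_name: str
    predicted_difficulty: float
    gm_units: int


def validate_ratings(candidate: Sequence[int]) -> ComponentRatings:
    """Validate an integer triple against the component rating schema.

    Parameters
    ----------
    candidate:
        Three values in the order (body position, movement, support).

    Returns
    -------
    ComponentRatings
        The validated triple.

    Raises
    ------
    ValidationError
        If there are not exactly three values, a value is not an
        integer, or a value lies outside its legal range. The message
        names the offending component and its range. Validation is
        strict: out-of-range values are rejected, never clamped.
    """
    values = list(candidate)
    if len(values) != 3:
        raise ValidationError(f"expected 3 component ratings, got {len(values)}")
    coerced = []
    for name, value in zip(RATING_RANGES, values):
        lo, hi = RATING_RANGES[name]
        # accept integer-valued floats/strings from file input, reject the rest
        if isinstance(value, bool):
            raise ValidationError(f"{name} rating must be an integer in [{lo}, {hi}], got {value!r}")
        if isinstance(value, float):
            if not value.is_integer():
                raise ValidationError(
                    f"{name} rating must be an integer in [{lo}, {hi}], got {value!r}"
                )
            value = int(value)
        elif isinstance(value, str):
            try:
                value = int(value.strip())
            except ValueError:
                raise ValidationError(
                    f"{name} rating must be an integer in [{lo}, {hi}], got {value!r}"
                ) from None
        coerced.append(value)
    return ComponentRatings(*coerced)


_TASK_COLUMNS = ["item_number", "item_name", "body_position", "movement", "support"]


def read_task_table(source: Union[str, Path, TextIO]) -> TaskTable:
    """Read a task-rating CSV into a validated :class:`TaskTable`.

    The file must carry a header with columns
    ``item_number,item_name,body_position,movement,support``. Row order
    is preserved. Any missing column, duplicate item number, or rating
    that fails validation raises :class:`ParseError` citing the data row
    number (header excluded).
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="", encoding="utf-8") as handle:
            return read_task_table(handle)

    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        raise ParseError("empty file: no header row")
    missing = [c for c in _TASK_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")

    tasks: list[GrossMotorTask] = []
    seen: set[int] = set()
    for row_no, row in enumerate(reader, start=1):
        try:
            item_number = int(row["item_number"])
            ratings = validate_ratings(
                [row["body_position"], row["movement"], row["support"]]
            )
            task = GrossMotorTask(item_number, row["item_name"], ratings)
        except (ValidationError, ValueError, TypeError) as exc:
            raise ParseError(f"row {row_no}: {exc}") from exc
        if item_number in seen:
            raise ParseError(f"row {row_no}: duplicate item_number {item_number}")
        seen.add(item_number)
        tasks.append(task)
    if not tasks:
        raise ParseError("no tasks: file contains a header but no data rows")
    return TaskTable(tuple(tasks))


def write_task_table(table: TaskTable, dest: Union[str, Path, TextIO]) -> None:
    """Write a :class:`TaskTable` as the canonical task-rating CSV."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", newline="", encoding="utf-8") as handle:
            write_task_table(table, handle)
        return
    writer = csv.writer(dest)
    writer.writerow(_TASK_COLUMNS)
    for task in table:
        writer.writerow(
            [
                task.item_number,
                task.item_name,
                task.ratings.body_position,
                task.ratings.movement,
                task.ratings.support,
            ]
        )


def _bundled_text(filename: str) -> str:
    return resources.files("gmunit.data").joinpath(filename).read_text(encoding="utf-8")


def bundled_gmfm_ratings() -> TaskTable:
    """The bundled 66-item GMFM-66 component-rating table, in item order."""
    return read_task_table(io.StringIO(_bundled_text("gmfm_ratings.csv")))


def bundled_reference_table() -> tuple[ReferenceRow, ...]:
    """The bundled 66-row GM-unit reference table, ordered by GM units.

    Each row pairs an item's predicted difficulty (specification-equation
    metric, two decimals) with its integer measure in GM units.
    """
    reader = csv.DictReader(io.StringIO(_bundled_text("gm_reference.csv")))
    rows = tuple(
        ReferenceRow(
            item_number=int(row["item_number"]),
            item_name=row["item_name"],
            predicted_difficulty=float(row["predicted_difficulty"]),
            gm_units=int(row["gm_units"]),
        )
        for row in reader
    )
    return rows
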