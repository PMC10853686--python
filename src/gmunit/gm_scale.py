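"""Anchored Gross Motor (GM) unit scale.

The specification equation predicts task difficulty on an arbitrary
interval metric. To give the metric a reproducible origin and unit size,
the scale is algebraically anchored to two universally recognised tasks
(the same device that pins Celsius to the freezing and boiling points of
water):

* low anchor — lying supine bringing hands to midline, assigned 0 GM
  units (predicted difficulty 14.13 under the published equation);
* high anchor — walking with hands free, assigned 100 GM units
  (predicted difficulty 61.88).

One GM unit is therefore 1/100 of the difficulty distance between lying
supine and unsupported walking, and the transform is

    GM = (TaskDifficulty - 14.13) * 2.09

with offset -14.13 and scale 2.09 = 100 / 47.75 rounded to two decimals.
The two-decimal constants are the default because they — and not the
exact ratio 100/47.75 ~ 2.0942 — reproduce every integer in the
published reference table (items 35 and 62 print 84 and item 68 prints
89 only under scale 2.09). An exact, unrounded mode is available via
``rounding_dp=None`` for theoretical work.

The scale extends beyond both anchors: tasks harder than unsupported
walking (stairs, jumping, hopping) measure above 100 GM units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from ._rounding import round_half_away
from .spec_equation import SpecificationEquation, predict_difficulty, published_equation
from .task_schema import (
    ComponentRatings,
    ReferenceRow,
    TaskTable,
    bundled_gmfm_ratings,
    bundled_reference_table,
)

__all__ = [
    "AnchorConstants",
    "GMValue",
    "Mismatch",
    "DEFAULT_LOW_ANCHOR_ITEM",
    "DEFAULT_HIGH_ANCHOR_ITEM",
    "derive_anchors",
    "default_anchors",
    "to_gm",
    "from_gm",
    "measure_task",
    "reproduce_reference_table",
    "person_measure_to_gm",
]

#: "Supine: brings hands to midline" — the first task a newborn can do.
DEFAULT_LOW_ANCHOR_ITEM = 2
#: "Standing: walk, hands free" — the walking milestone.
DEFAULT_HIGH_ANCHOR_ITEM = 69


class GMValue(NamedTuple):
    """A measure in GM units: raw, and rounded to the nearest integer
    (ties away from zero), the precision at which GM units are reported."""

    raw: float
    rounded: int


@dataclass(frozen=True)
class AnchorConstants:
    """Offset and unit-size constants fixing the GM scale.

    ``offset`` is the negative of the low anchor's predicted difficulty;
    ``scale`` is GM units per difficulty unit. With the default anchor
    values (0 and 100) the transform is
    ``raw_gm = (difficulty + offset) * scale``; for a nonzero low anchor
    value the map generalises to
    ``raw_gm = low_anchor_value + (difficulty + offset) * scale``.
    ``rounding_dp`` records the decimal precision the constants were
    rounded to at derivation (None = exact mode).
    """

    offset: float
    scale: float
    low_anchor_value: float = 0.0
    high_anchor_value: float = 100.0
    rounding_dp: Optional[int] = 2
    low_anchor_item: Optional[int] = DEFAULT_LOW_ANCHOR_ITEM
    high_anchor_item: Optional[int] = DEFAULT_HIGH_ANCHOR_ITEM

    def __post_init__(self) -> None:
        if not (np.isfinite(self.offset) and np.isfinite(self.scale)):
            raise ValueError("anchor constants must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not self.low_anchor_value < self.high_anchor_value:
            raise ValueError("low anchor value must be below high anchor value")


def derive_anchors(
    pred_low: float,
    pred_high: float,
    low_value: float = 0.0,
    high_value: float = 100.0,
    rounding_dp: Optional[int] = 2,
    low_item: Optional[int] = DEFAULT_LOW_ANCHOR_ITEM,
    high_item: Optional[int] = DEFAULT_HIGH_ANCHOR_ITEM,
) -> AnchorConstants:
    """Derive anchoring constants from two predicted difficulties.

    offset = -pred_low and scale = (high_value - low_value) /
    (pred_high - pred_low), each then rounded to ``rounding_dp``
    decimals (``rounding_dp=None`` keeps them exact).

    Raises
    ------
    ValueError
        If ``pred_low >= pred_high`` (degenerate or inverted anchors).
    """
    if not pred_low < pred_high:
        raise ValueError(
            f"low anchor difficulty ({pred_low}) must be strictly below "
            f"high anchor difficulty ({pred_high})"
        )
    offset = -float(pred_low)
    scale = (float(high_value) - float(low_value)) / (float(pred_high) - float(pred_low))
    if rounding_dp is not None:
        offset = round_half_away(offset, rounding_dp)
        scale = round_half_away(scale, rounding_dp)
    return AnchorConstants(
        offset=offset,
        scale=scale,
        low_anchor_value=float(low_value),
        high_anchor_value=float(high_value),
        rounding_dp=rounding_dp,
        low_anchor_item=low_item,
        high_anchor_item=high_item,
    )


def default_anchors(
    equation: Optional[SpecificationEquation] = None,
    table: Optional[TaskTable] = None,
    rounding_dp: Optional[int] = 2,
) -> AnchorConstants:
    """Anchors from the bundled anchor items under ``equation``.

    Uses the 2-dp predicted difficulties of the low anchor (item 2,
    supine hands to midline -> 0 GM) and high anchor (item 69, walking
    hands free -> 100 GM). Defaults to the published equation and the
    bundled rating table.
    """
    equation = equation or published_equation()
    table = table or bundled_gmfm_ratings()
    pred_low = predict_difficulty(equation, table[DEFAULT_LOW_ANCHOR_ITEM].ratings).rounded
    pred_high = predict_difficulty(equation, table[DEFAULT_HIGH_ANCHOR_ITEM].ratings).rounded
    return derive_anchors(pred_low, pred_high, rounding_dp=rounding_dp)


def to_gm(pred_difficulty: float, constants: AnchorConstants) -> GMValue:
    """Map a predicted difficulty onto the GM scale."""
    raw = constants.low_anchor_value + (float(pred_difficulty) + constants.offset) * constants.scale
    return GMValue(raw=raw, rounded=int(round_half_away(raw, 0)))


def from_gm(gm: float, constants: AnchorConstants) -> float:
    """Inverse of :func:`to_gm` on raw values.

    Note that with constants rounded at derivation (the 2-dp default)
    the inverse of the *rounded* anchor targets is slightly asymmetric:
    100 GM maps back to 100/2.09 + 14.13 = 61.97..., not the 61.88 the
    anchors were derived from. The round trip to_gm(from_gm(x)) is still
    the exact identity.
    """
    return (float(gm) - constants.low_anchor_value) / constants.scale - constants.offset


def measure_task(
    ratings: ComponentRatings,
    equation: Optional[SpecificationEquation] = None,
    constants: Optional[AnchorConstants] = None,
) -> GMValue:
    """Measure one task in GM units from its component ratings.

    Predicted difficulty is computed from the equation, rounded to two
    decimals (the precision at which difficulties are reported and at
    which the reference table was built), then passed through the
    anchored transform.
    """
    equation = equation or published_equation()
    constants = constants or default_anchors(equation)
    pred = predict_difficulty(equation, ratings).rounded
    return to_gm(pred, constants)


class Mismatch(NamedTuple):
    """One cell-level disagreement with the bundled reference table."""

    item_number: int
    field: str
    expected: float
    actual: float


def reproduce_reference_table(
    equation: Optional[SpecificationEquation] = None,
    constants: Optional[AnchorConstants] = None,
    table: Optional[TaskTable] = None,
) -> tuple[tuple[ReferenceRow, ...], tuple[Mismatch, ...]]:
    """Recompute the full GM reference table and diff it cell-by-cell.

    For every task: predicted difficulty at 2 dp and integer GM units,
    rows sorted by GM units (predicted difficulty, then item number, as
    tie-breaks). The diff compares each item's pair against the bundled
    reference; an empty diff means the pipeline reproduces the published
    table exactly.
    """
    equation = equation or published_equation()
    table = table or bundled_gmfm_ratings()
    constants = constants or default_anchors(equation, table)

    rows = []
    for task in table:
        pred = predict_difficulty(equation, task.ratings).rounded
        gm = to_gm(pred, constants).rounded
        rows.append(
            ReferenceRow(
                item_number=task.item_number,
                item_name=task.item_name,
                predicted_difficulty=pred,
                gm_units=gm,
            )
        )
    rows.sort(key=lambda r: (r.gm_units, r.predicted_difficulty, r.item_number))

    expected = {row.item_number: row for row in bundled_reference_table()}
    mismatches: list[Mismatch] = []
    for row in rows:
        ref = expected.get(row.item_number)
        if ref is None:
            continue  # non-bundled task: nothing to diff against
        if abs(row.predicted_difficulty - ref.predicted_difficulty) > 5e-3:
            mismatches.append(
                Mismatch(row.item_number, "predicted_difficulty",
                         ref.predicted_difficulty, row.predicted_difficulty)
            )
        if row.gm_units != ref.gm_units:
            mismatches.append(
                Mismatch(row.item_number, "gm_units", ref.gm_units, row.gm_units)
            )
    return tuple(rows), tuple(mismatches)


def person_measure_to_gm(ability: float, constants: AnchorConstants) -> GMValue:
    """Express a person ability in GM units.

    The ability must already live on the same interval metric as
    predicted task difficulty (e.g. a calibrated Rasch ability rescaled
    to that metric); it is then passed through the identical affine
    anchor map as task difficulties. Extending the anchored transform
    from task difficulty to person measures goes beyond the published
    derivation and is provided as a convenience for ability reporting.
    """
    return to_gm(ability, constants)
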