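"""Table-driven clinical risk scores: Khorana, ThroLy and modified ThroLy.

A score is a :class:`ScoringTable`: an ordered list of items, each worth a
fixed number of points when its condition(s) hold on a patient, plus a band
rule mapping the integer total to low / intermediate / high risk.  The two
shipped defaults encode the published Khorana score (chemotherapy-associated
VTE in cancer; high risk >= 3) and the lymphoma-specific ThroLy score (high
risk > 3, intermediate 2-3, low 0-1).  Item sets and band breakpoints are
configuration (JSON), never hard-coded logic, so local variants are one file
away.

An item's conditions are OR-combined; an item with no conditions always fires
(used for the Khorana cancer-site point, fixed at 1 for lymphoma).  A
condition on a field that is unknown for the patient evaluates false and a
warning is emitted: retrospective registries are incomplete, and a silent
zero with an audit trail is the least surprising rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Literal, Optional

from .cohort import PatientRecord, RISK_BANDS

logger = logging.getLogger(__name__)

Comparator = Literal["lt", "le", "gt", "ge", "eq", "flag"]

_COMPARE = {
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
    "eq": lambda v, t: v == t,
}


@dataclass(frozen=True)
class Condition:
    """One predicate over a patient field: ``field op threshold`` or a flag."""

    field: str
    op: Comparator
    threshold: Optional[float] = None

    def evaluate(self, record: PatientRecord) -> bool:
        value = record.get_field(self.field)
        if value is None:
            logger.warning(
                "field %r unknown for patient %r; condition treated as false",
                self.field,
                record.id,
            )
            return False
        if self.op == "flag":
            return bool(value)
        return _COMPARE[self.op](value, self.threshold)


@dataclass(frozen=True)
class ScoringItem:
    name: str
    points: int
    conditions: tuple[Condition, ...] = ()

    def __post_init__(self) -> None:
        if self.points < 1:
            raise ValueError(f"item {self.name!r}: points must be >= 1")

    def applies(self, record: PatientRecord) -> bool:
        # empty condition list = unconditional item (e.g. cancer-site point)
        if not self.conditions:
            return True
        return any(c.evaluate(record) for c in self.conditions)


@dataclass(frozen=True)
class ScoringTable:
    """Named item list plus band breakpoints.

    ``low_max`` is the largest total still classified low; ``intermediate_max``
    the largest total still intermediate; anything above is high.  This two-
    breakpoint form expresses both Khorana (0 | 1-2 | >=3) and ThroLy
    (0-1 | 2-3 | >3).
    """

    name: str
    items: tuple[ScoringItem, ...]
    low_max: int
    intermediate_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.low_max < self.intermediate_max):
            raise ValueError(
                "band rule requires 0 <= low_max < intermediate_max "
                f"(got {self.low_max}, {self.intermediate_max})"
            )


def score(record: PatientRecord, table: ScoringTable) -> int:
    """Total points for *record* under *table* (sum over items that apply)."""
    return sum(item.points for item in table.items if item.applies(record))


def score_breakdown(record: PatientRecord, table: ScoringTable) -> dict[str, int]:
    """Per-item audit: item name -> points awarded (0 if not applicable)."""
    return {
        item.name: (item.points if item.applies(record) else 0)
        for item in table.items
    }


def classify(total: int, table: ScoringTable) -> str:
    """Map an integer total to its risk band under the table's band rule."""
    if total < 0:
        raise ValueError("score total must be non-negative")
    if total <= table.low_max:
        return "low"
    if total <= table.intermediate_max:
        return "intermediate"
    return "high"


def make_mthroly(base: ScoringTable, hb_cutoff: float = 110.0) -> ScoringTable:
    """Raise the hemoglobin threshold of a ThroLy-style table.

    The modified ThroLy score moves the anemia item from Hb < 100 g/L to
    Hb < 110 g/L (hemoglobin >= 110 g/L being protective, the boundary value
    110 earns no point).  The base table must contain exactly one item with a
    condition on ``hb``; everything else is copied unchanged.
    """
    hb_items = [
        i for i, item in enumerate(base.items)
        if any(c.field == "hb" for c in item.conditions)
    ]
    if len(hb_items) != 1:
        raise ValueError(
            f"table {base.name!r} must contain exactly one hemoglobin item, "
            f"found {len(hb_items)}"
        )
    idx = hb_items[0]
    old = base.items[idx]
    new_conditions = tuple(
        replace(c, threshold=float(hb_cutoff)) if c.field == "hb" else c
        for c in old.conditions
    )
    new_items = list(base.items)
    new_items[idx] = replace(old, conditions=new_conditions)
    return replace(base, name=f"m{base.name}", items=tuple(new_items))


# ---------------------------------------------------------------------------
# JSON (de)serialisation and shipped defaults


def table_from_dict(d: dict) -> ScoringTable:
    items = []
    for it in d["items"]:
        conds = tuple(
            Condition(c["field"], c["op"], c.get("threshold"))
            for c in it.get("conditions", [])
        )
        items.append(ScoringItem(it["name"], int(it["points"]), conds))
    bands = d["bands"]
    return ScoringTable(
        name=d["name"],
        items=tuple(items),
        low_max=int(bands["low_max"]),
        intermediate_max=int(bands["intermediate_max"]),
    )


def table_to_dict(table: ScoringTable) -> dict:
    return {
        "name": table.name,
        "items": [
            {
                "name": it.name,
                "points": it.points,
                "conditions": [
                    {"field": c.field, "op": c.op}
                    | ({} if c.threshold is None else {"threshold": c.threshold})
                    for c in it.conditions
                ],
            }
            for it in table.items
        ],
        "bands": {"low_max": table.low_max, "intermediate_max": table.intermediate_max},
    }


def load_table(path_or_name: str) -> ScoringTable:
    """Load a scoring table from a JSON file path or a shipped default name.

    Shipped defaults: ``"khorana"`` and ``"throly"``.
    """
    if path_or_name in ("khorana", "throly"):
        text = (
            resources.files("lymphovte.data")
            .joinpath(f"{path_or_name}.json")
            .read_text()
        )
    else:
        with open(path_or_name) as fh:
            text = fh.read()
    return table_from_dict(json.loads(text))


def khorana_table() -> ScoringTable:
    return load_table("khorana")


def throly_table() -> ScoringTable:
    return load_table("throly")


def mthroly_table(hb_cutoff: float = 110.0) -> ScoringTable:
    return make_mthroly(throly_table(), hb_cutoff)
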