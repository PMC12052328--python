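"""Definition and loading of the rated food-knowledge instrument.

The instrument is an ordered set of food items, each belonging to a food
category (banana, beef, corn, dairy in the bundled default) and to one of
three Nova food-processing groups:

* ``G1`` — unprocessed and minimally processed foods,
* ``G3`` — processed foods,
* ``G4`` — ultra-processed foods.

Processed culinary ingredients (Nova G2) are never part of an instrument:
they are not consumed on their own, so there is nothing for a respondent to
rate. Respondents rate each item's healthiness on a bounded integer scale
(1-10 by default); knowledge is then scored from how well the within-category
ratings recover the ordering G1 > G3 > G4 (see :mod:`novascore.scoring`).

Every category must be a complete triad — exactly one item from each of G1,
G3 and G4 — which the loader enforces. Presentation order of items to a
respondent is a data-collection concern and is not represented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Union

from .errors import InstrumentError

__all__ = [
    "NovaGroup",
    "RatingScale",
    "FoodItem",
    "Instrument",
    "load_instrument",
    "loads_instrument",
    "default_instrument",
]


class NovaGroup(str, Enum):
    """Nova food-processing groups that can appear in an instrument.

    G2 (processed culinary ingredients) is deliberately absent.
    """

    G1 = "G1"
    G3 = "G3"
    G4 = "G4"


#: Canonical within-category healthiness ordering: G1 healthiest, G4 least.
GROUP_ORDER = (NovaGroup.G1, NovaGroup.G3, NovaGroup.G4)


@dataclass(frozen=True)
class RatingScale:
    """Inclusive integer bounds of the healthiness rating scale."""

    min: int = 1
    max: int = 10

    def __post_init__(self) -> None:
        if not (isinstance(self.min, int) and isinstance(self.max, int)):
            raise InstrumentError("rating scale bounds must be integers")
        if self.min >= self.max:
            raise InstrumentError(
                f"rating scale must satisfy min < max, got ({self.min}, {self.max})"
            )

    def contains(self, rating: int) -> bool:
        return self.min <= rating <= self.max


@dataclass(frozen=True)
class FoodItem:
    """One rated food item: a member of a category's Nova triad."""

    item_id: str
    label: str
    category: str
    nova_group: NovaGroup


@dataclass(frozen=True)
class Instrument:
    """A validated rated-food instrument.

    ``categories`` preserves first-appearance order of the item list, and
    every category is guaranteed at construction to contain exactly one item
    per Nova group.
    """

    name: str
    items: tuple[FoodItem, ...]
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        _validate_items(self.items)

    @property
    def categories(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.category, None)
        return tuple(seen)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def item(self, item_id: str) -> FoodItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def triad(self, category: str) -> dict[NovaGroup, FoodItem]:
        """The (G1, G3, G4) items of one category, keyed by group."""
        triad = {it.nova_group: it for it in self.items if it.category == category}
        if not triad:
            raise KeyError(category)
        return triad

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale": {"min": self.scale.min, "max": self.scale.max},
            "items": [
                {
                    "item_id": it.item_id,
                    "label": it.label,
                    "category": it.category,
                    "nova_group": it.nova_group.value,
                }
                for it in self.items
            ],
        }

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def _validate_items(items: tuple[FoodItem, ...]) -> None:
    if not items:
        raise InstrumentError("instrument has no items")
    seen_ids: set[str] = set()
    for it in items:
        if it.item_id in seen_ids:
            raise InstrumentError(f"duplicate item_id {it.item_id!r}")
        seen_ids.add(it.item_id)
    by_category: dict[str, list[NovaGroup]] = {}
    for it in items:
        by_category.setdefault(it.category, []).append(it.nova_group)
    for category, groups in by_category.items():
        missing = [g.value for g in GROUP_ORDER if g not in groups]
        if missing:
            raise InstrumentError(
                f"category {category!r} is missing group(s) {', '.join(missing)}: "
                "each category needs exactly one G1, G3 and G4 item"
            )
        if len(groups) != len(GROUP_ORDER):
            dupes = sorted({g.value for g in groups if groups.count(g) > 1})
            raise InstrumentError(
                f"category {category!r} has more than one item in group(s) "
                f"{', '.join(dupes)}"
            )


def _parse_document(doc: dict, source: str) -> Instrument:
    if not isinstance(doc, dict):
        raise InstrumentError(f"{source}: instrument document must be a JSON object")
    for key in ("name", "scale", "items"):
        if key not in doc:
            raise InstrumentError(f"{source}: missing required key {key!r}")
    scale_doc = doc["scale"]
    if not isinstance(scale_doc, dict) or not {"min", "max"} <= scale_doc.keys():
        raise InstrumentError(f"{source}: scale must be an object with 'min' and 'max'")
    scale = RatingScale(scale_doc["min"], scale_doc["max"])
    items = []
    for i, row in enumerate(doc["items"]):
        if not isinstance(row, dict):
            raise InstrumentError(f"{source}: item {i} is not an object")
        missing = {"item_id", "label", "category", "nova_group"} - row.keys()
        if missing:
            raise InstrumentError(
                f"{source}: item {i} missing field(s) {', '.join(sorted(missing))}"
            )
        try:
            group = NovaGroup(row["nova_group"])
        except ValueError:
            raise InstrumentError(
                f"{source}: item {row['item_id']!r} has unknown nova_group "
                f"{row['nova_group']!r} (expected G1, G3 or G4)"
            ) from None
        items.append(
            FoodItem(
                item_id=str(row["item_id"]),
                label=str(row["label"]),
                category=str(row["category"]),
                nova_group=group,
            )
        )
    return Instrument(name=str(doc["name"]), items=tuple(items), scale=scale)


def loads_instrument(text: str, source: str = "<string>") -> Instrument:
    """Parse an instrument from a JSON string."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise InstrumentError(f"{source}: not valid JSON ({exc})") from exc
    return _parse_document(doc, source)


def load_instrument(path: Union[str, Path]) -> Instrument:
    """Load and validate an instrument from a JSON document on disk."""
    path = Path(path)
    return loads_instrument(path.read_text(encoding="utf-8"), source=str(path))


def default_instrument() -> Instrument:
    """The bundled 12-item Nova-Conhecimento instrument.

    Four categories (banana, beef, corn, dairy), each a complete G1/G3/G4
    triad, rated on a 1-10 scale.
    """
    text = (
        resources.files("novascore.data")
        .joinpath("nova_conhecimento.json")
        .read_text(encoding="utf-8")
    )
    return loads_instrument(text, source="novascore.data/nova_conhecimento.json")
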