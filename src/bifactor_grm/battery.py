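"""Battery configuration: which scale each item belongs to and how it is coded.

The battery is the single source of truth for item order, response-scale size
(K), specific-factor membership and coding direction.  The default battery
mirrors a 30-item subjective well-being protocol: 10 positive-affect and 10
negative-affect adjectives on a 1-5 scale (negative affect negatively keyed),
plus 5 life-satisfaction and 5 harmony-in-life statements on a 1-7 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ItemSpec", "Battery", "make_paper_battery", "read_battery", "write_battery"]


@dataclass(frozen=True)
class ItemSpec:
    item_id: str
    scale_id: str
    specific_factor_index: int  # 1-based, contiguous across the battery
    n_categories: int
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError(f"item {self.item_id}: need >=2 categories")
        if self.specific_factor_index < 1:
            raise ValueError(f"item {self.item_id}: specific factor index must be >=1")


@dataclass(frozen=True)
class Battery:
    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in battery")
        fac = sorted({it.specific_factor_index for it in self.items})
        if fac != list(range(1, len(fac) + 1)):
            raise ValueError(f"specific factor indices must be contiguous from 1, got {fac}")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_specific_factors(self) -> int:
        return max(it.specific_factor_index for it in self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def scale_ids(self) -> list[str]:
        """Scale label per item, battery order."""
        return [it.scale_id for it in self.items]

    @property
    def factor_index(self):
        """0-based specific factor index per item as an array-friendly list."""
        return [it.specific_factor_index - 1 for it in self.items]

    def items_for_factor(self, factor_index: int) -> list[int]:
        """Positions of the items loading on a given 1-based specific factor."""
        return [i for i, it in enumerate(self.items) if it.specific_factor_index == factor_index]

    def items_for_scale(self, scale_id: str) -> list[int]:
        return [i for i, it in enumerate(self.items) if it.scale_id == scale_id]

    @property
    def scales(self) -> list[str]:
        seen: list[str] = []
        for it in self.items:
            if it.scale_id not in seen:
                seen.append(it.scale_id)
        return seen

    def to_records(self) -> list[dict]:
        return [
            {
                "item_id": it.item_id,
                "scale_id": it.scale_id,
                "specific_factor_index": it.specific_factor_index,
                "n_categories": it.n_categories,
                "reverse_coded": it.reverse_coded,
            }
            for it in self.items
        ]

    @classmethod
    def from_records(cls, records) -> "Battery":
        return cls(items=tuple(ItemSpec(**r) for r in records))


def make_paper_battery() -> Battery:
    """The 30-item tridimensional well-being battery.

    10 positive-affect (PA, K=5, specific factor 1), 10 negative-affect
    (NA, K=5, specific factor 2, negatively keyed hence reverse-coded before
    analysis), 5 life-satisfaction (LS, K=7, specific factor 3) and 5
    harmony-in-life (HIL, K=7, specific factor 4) items.
    """
    items: list[ItemSpec] = []
    for i in range(1, 11):
        items.append(ItemSpec(f"PA{i:02d}", "PA", 1, 5, False))
    for i in range(1, 11):
        items.append(ItemSpec(f"NA{i:02d}", "NA", 2, 5, True))
    for i in range(1, 6):
        items.append(ItemSpec(f"LS{i:02d}", "LS", 3, 7, False))
    for i in range(1, 6):
        items.append(ItemSpec(f"HIL{i:02d}", "HIL", 4, 7, False))
    return Battery(items=tuple(items))


def write_battery(battery: Battery, path: str | Path) -> None:
    """Write a battery config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    records = battery.to_records()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"items": records}, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump({"items": records}, sort_keys=False))


def read_battery(path: str | Path) -> Battery:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return Battery.from_records(data["items"])
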