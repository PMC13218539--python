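"""The 20-nutrient panel used throughout the package.

Energy (kcal) is tracked separately from the panel. The panel splits into
three blocks:

* 4 macronutrients (g): protein, fat, carbohydrate, fiber;
* 11 micronutrients entering the Mean Adequacy Ratio (MAR): calcium, iron,
  zinc, vitamins A/C/B6/B12, thiamin, riboflavin, niacin, folate;
* 5 limit ("diet quality") nutrients carrying an upper limit instead of an
  RDI: sodium, saturated fat, total sugars, cholesterol, added sugars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ENERGY = "energy_kcal"

MACROS = ("protein", "fat", "carbohydrate", "fiber")

MAR_MICROS = (
    "calcium",
    "iron",
    "zinc",
    "vitamin_a",
    "vitamin_c",
    "vitamin_b6",
    "vitamin_b12",
    "thiamin",
    "riboflavin",
    "niacin",
    "folate",
)

LIMIT_NUTRIENTS = (
    "sodium",
    "saturated_fat",
    "total_sugars",
    "cholesterol",
    "added_sugars",
)

_UNITS = {
    "protein": "g",
    "fat": "g",
    "carbohydrate": "g",
    "fiber": "g",
    "calcium": "mg",
    "iron": "mg",
    "zinc": "mg",
    "vitamin_a": "ug_rae",
    "vitamin_c": "mg",
    "vitamin_b6": "mg",
    "vitamin_b12": "ug",
    "thiamin": "mg",
    "riboflavin": "mg",
    "niacin": "mg",
    "folate": "ug_dfe",
    "sodium": "mg",
    "saturated_fat": "g",
    "total_sugars": "g",
    "cholesterol": "mg",
    "added_sugars": "g",
}


@dataclass(frozen=True)
class NutrientPanel:
    """Named nutrient panel with unit strings and block membership.

    Invariants: exactly 11 nutrients are flagged as MAR micronutrients;
    limit nutrients carry an upper limit, adequacy nutrients an RDI.
    """

    macros: tuple[str, ...] = MACROS
    micros: tuple[str, ...] = MAR_MICROS
    limits: tuple[str, ...] = LIMIT_NUTRIENTS
    units: dict[str, str] = field(default_factory=lambda: dict(_UNITS))

    def __post_init__(self) -> None:
        if len(self.micros) != 11:
            raise ValueError(f"MAR requires exactly 11 micronutrients, got {len(self.micros)}")
        for n in self.names:
            if n not in self.units:
                raise ValueError(f"nutrient {n!r} has no unit")

    @property
    def names(self) -> tuple[str, ...]:
        """All 20 panel nutrients, in canonical order (energy excluded)."""
        return self.macros + self.micros + self.limits

    @property
    def adequacy(self) -> tuple[str, ...]:
        """Nutrients scored against an RDI (macros with an RDI + micros)."""
        return ("protein", "fiber") + self.micros

    def is_limit(self, name: str) -> bool:
        return name in self.limits


DEFAULT_PANEL = NutrientPanel()


def atwater_energy(protein: float, carbohydrate: float, fat: float) -> float:
    """Atwater energy (kcal) from macro grams: 4p + 4c + 9f."""
    return 4.0 * protein + 4.0 * carbohydrate + 9.0 * fat
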