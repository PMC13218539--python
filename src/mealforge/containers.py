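"""In-memory containers: the food catalog and the meal corpus.

Both are thin wrappers over pandas DataFrames in the same long/wide layouts
used on disk (see :mod:`mealforge.io`), with validation of the package-wide
invariants (non-negative densities, positive grams, no duplicate food codes
within a meal) and the vectorised accessors downstream stages need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mealforge.nutrients import DEFAULT_PANEL, ENERGY, NutrientPanel

MEAL_TYPES = ("breakfast", "lunch", "dinner")


@dataclass
class FoodCatalog:
    """Foods with categories and per-gram nutrient densities.

    ``df`` is indexed by food code with columns ``main_category``,
    ``subcategory``, ``is_beverage``, ``energy_kcal`` and one column per
    panel nutrient (all densities per gram).
    """

    df: pd.DataFrame
    panel: NutrientPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        required = ["main_category", "subcategory", "is_beverage", ENERGY, *self.panel.names]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"catalog missing columns: {missing}")
        dens = self.df[[ENERGY, *self.panel.names]].to_numpy(dtype=float)
        if (dens < 0).any():
            raise ValueError("nutrient densities must be non-negative")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()].tolist()
            raise ValueError(f"duplicate food codes: {dup}")

    @property
    def codes(self) -> list[str]:
        return list(self.df.index)

    @property
    def categories(self) -> list[str]:
        return sorted(self.df["main_category"].unique())

    @property
    def subcategories(self) -> list[str]:
        return sorted(self.df["subcategory"].unique())

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, code: str) -> bool:
        return code in self.df.index

    def density_matrix(self, include_energy: bool = True) -> pd.DataFrame:
        """Per-gram densities, foods x nutrients (energy first if included)."""
        cols = ([ENERGY] if include_energy else []) + list(self.panel.names)
        return self.df[cols]

    def energy_density(self) -> pd.Series:
        return self.df[ENERGY]

    def is_beverage(self) -> pd.Series:
        return self.df["is_beverage"].astype(bool)

    def subset(self, codes) -> "FoodCatalog":
        return FoodCatalog(self.df.loc[list(codes)].copy(), self.panel)


@dataclass
class MealCorpus:
    """Meals as (food code, grams) lists with time-of-day labels.

    ``df`` is long-format with one row per meal item: columns ``meal_id``,
    ``meal_type``, ``food_code``, ``grams`` and optional integer
    ``true_archetype`` (synthetic ground truth; -1 when unknown).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["meal_id", "meal_type", "food_code", "grams"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"corpus missing columns: {missing}")
        if "true_archetype" not in self.df.columns:
            self.df = self.df.assign(true_archetype=-1)
        bad_type = set(self.df["meal_type"]) - set(MEAL_TYPES)
        if bad_type:
            raise ValueError(f"unknown meal types: {sorted(bad_type)}")
        grams = self.df["grams"].to_numpy(dtype=float)
        if (grams <= 0).any():
            rows = np.flatnonzero(grams <= 0).tolist()
            raise ValueError(f"grams must be > 0; offending rows: {rows[:10]}")
        dup = self.df.duplicated(subset=["meal_id", "food_code"])
        if dup.any():
            rows = np.flatnonzero(dup.to_numpy()).tolist()
            raise ValueError(f"duplicate food codes within a meal; rows: {rows[:10]}")

    @property
    def meal_ids(self) -> list[str]:
        return list(self.df["meal_id"].unique())

    @property
    def n_meals(self) -> int:
        return self.df["meal_id"].nunique()

    def __len__(self) -> int:
        return self.n_meals

    def meal_types(self) -> pd.Series:
        """meal_id -> meal_type."""
        return self.df.groupby("meal_id", sort=False)["meal_type"].first()

    def true_archetypes(self) -> pd.Series:
        """meal_id -> planted archetype label (-1 when unknown)."""
        return self.df.groupby("meal_id", sort=False)["true_archetype"].first()

    def items(self, meal_id: str) -> list[tuple[str, float]]:
        rows = self.df[self.df["meal_id"] == meal_id]
        return list(zip(rows["food_code"], rows["grams"].astype(float)))

    def item_counts(self) -> pd.Series:
        return self.df.groupby("meal_id", sort=False)["food_code"].size()

    def subset(self, meal_ids) -> "MealCorpus":
        keep = self.df["meal_id"].isin(set(meal_ids))
        return MealCorpus(self.df[keep].reset_index(drop=True).copy())

    def by_meal_type(self, meal_type: str) -> "MealCorpus":
        if meal_type not in MEAL_TYPES:
            raise ValueError(f"unknown meal type {meal_type!r}")
        return MealCorpus(self.df[self.df["meal_type"] == meal_type].reset_index(drop=True).copy())

    def validate_against(self, catalog: FoodCatalog) -> None:
        unknown = set(self.df["food_code"]) - set(catalog.df.index)
        if unknown:
            raise ValueError(f"meal references unknown food codes: {sorted(unknown)[:10]}")

    def gram_matrix(self, catalog: FoodCatalog) -> pd.DataFrame:
        """Meals x foods gram matrix (0 where absent), rows in meal order."""
        self.validate_against(catalog)
        wide = self.df.pivot_table(
            index="meal_id", columns="food_code", values="grams", aggfunc="sum", fill_value=0.0
        )
        wide = wide.reindex(columns=catalog.codes, fill_value=0.0)
        return wide.loc[self.meal_ids]

    def nutrient_totals(self, catalog: FoodCatalog) -> pd.DataFrame:
        """Per-meal nutrient totals (energy + the 20-nutrient panel) and grams."""
        grams = self.gram_matrix(catalog)
        dens = catalog.density_matrix().loc[grams.columns]
        totals = pd.DataFrame(
            grams.to_numpy() @ dens.to_numpy(), index=grams.index, columns=dens.columns
        )
        totals["total_grams"] = grams.to_numpy().sum(axis=1)
        return totals
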