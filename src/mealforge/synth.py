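"""Seeded synthetic meal corpora emulating dietary-recall structure.

The generator produces what a WWEIA-style intake survey looks like from the
modelling side without any of its content: a food catalog organised in a
category/subcategory taxonomy with Atwater-consistent per-gram nutrient
densities, and a sparse meal corpus in which each meal is drawn from one of
a small number of archetypes (cereal-bowl-like, entree-plus-sides-like, ...)
defined by a category-weight simplex, a Poisson item count, Zipf food
popularity within category, and lognormal gram amounts. The archetype each
meal was drawn from is recorded as ground truth so clustering and
generation can be scored against a planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mealforge.containers import MEAL_TYPES, FoodCatalog, MealCorpus
from mealforge.nutrients import DEFAULT_PANEL, ENERGY, MAR_MICROS, NutrientPanel, atwater_energy

# Category name pool; "beverages" is always present exactly once.
_CATEGORY_POOL = (
    "grains",
    "vegetables",
    "fruits",
    "dairy",
    "protein_foods",
    "mixed_dishes",
    "snacks_sweets",
    "beverages",
    "fats_oils",
    "soups",
    "condiments_sauces",
    "seafood",
    "legumes",
    "eggs",
)

# Per-gram macro density profiles (protein, fat, carbohydrate, fiber), g/g.
_MACRO_PROFILES = {
    "grains": (0.08, 0.03, 0.45, 0.040),
    "vegetables": (0.02, 0.004, 0.06, 0.025),
    "fruits": (0.007, 0.003, 0.13, 0.020),
    "dairy": (0.05, 0.055, 0.06, 0.0),
    "protein_foods": (0.20, 0.10, 0.02, 0.0),
    "mixed_dishes": (0.08, 0.08, 0.15, 0.015),
    "snacks_sweets": (0.05, 0.20, 0.60, 0.020),
    "beverages": (0.003, 0.002, 0.09, 0.001),
    "fats_oils": (0.01, 0.70, 0.02, 0.0),
    "soups": (0.03, 0.02, 0.05, 0.008),
    "condiments_sauces": (0.02, 0.10, 0.20, 0.005),
    "seafood": (0.20, 0.05, 0.01, 0.0),
    "legumes": (0.09, 0.02, 0.20, 0.065),
    "eggs": (0.12, 0.10, 0.01, 0.0),
}
_DEFAULT_MACRO_PROFILE = (0.06, 0.05, 0.15, 0.010)

# Typical per-item gram scale per category (lognormal median).
_GRAM_MEDIANS = {
    "grains": 60.0,
    "vegetables": 85.0,
    "fruits": 120.0,
    "dairy": 200.0,
    "protein_foods": 110.0,
    "mixed_dishes": 250.0,
    "snacks_sweets": 40.0,
    "beverages": 240.0,
    "fats_oils": 14.0,
    "soups": 240.0,
    "condiments_sauces": 20.0,
    "seafood": 110.0,
    "legumes": 90.0,
    "eggs": 50.0,
}
_DEFAULT_GRAM_MEDIAN = 100.0

# Daily reference values used to scale synthetic micronutrient densities so
# that realistic meals land near (but mostly below) full adequacy.
DAILY_RDI = {
    "calcium": 1000.0,
    "iron": 8.0,
    "zinc": 11.0,
    "vitamin_a": 900.0,
    "vitamin_c": 90.0,
    "vitamin_b6": 1.3,
    "vitamin_b12": 2.4,
    "thiamin": 1.2,
    "riboflavin": 1.3,
    "niacin": 16.0,
    "folate": 400.0,
    "protein": 50.0,
    "fiber": 28.0,
}

DAILY_LIMITS = {
    "sodium": 2300.0,
    "saturated_fat": 20.0,
    "total_sugars": 90.0,  # lenient descriptive marker; guidance limits added sugars
    "cholesterol": 300.0,
    "added_sugars": 50.0,
}


def category_names(n_categories: int) -> list[str]:
    """Deterministic category list: pool names first, synthetic fill after.

    "beverages" is always included so beverage constraints are exercised.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories (one must be beverages)")
    if n_categories <= len(_CATEGORY_POOL):
        names = list(_CATEGORY_POOL[:n_categories])
        if "beverages" not in names:
            names[-1] = "beverages"
    else:
        names = list(_CATEGORY_POOL)
        names += [f"category_{i}" for i in range(n_categories - len(names))]
    return names


def generate_catalog(
    n_foods: int,
    n_categories: int,
    seed: int,
    panel: NutrientPanel = DEFAULT_PANEL,
) -> FoodCatalog:
    """Generate a synthetic food catalog.

    Foods are assigned to categories round-robin, each category is split
    into two subcategories, and each food's energy density is held within
    5% of its Atwater value 4p + 4c + 9f. The beverages category is
    low-energy (mean below 1 kcal/g).
    """
    if n_foods < n_categories:
        raise ValueError(f"n_foods ({n_foods}) must be >= n_categories ({n_categories})")
    rng = np.random.default_rng(seed)
    cats = category_names(n_categories)

    rows = []
    for i in range(n_foods):
        cat = cats[i % n_categories]
        sub = f"{cat}/{(i // n_categories) % 2 + 1}"
        base = _MACRO_PROFILES.get(cat, _DEFAULT_MACRO_PROFILE)
        jitter = rng.lognormal(mean=0.0, sigma=0.25, size=4)
        protein, fat, carb, fiber = (b * j for b, j in zip(base, jitter))
        energy = atwater_energy(protein, carb, fat) * (1.0 + rng.uniform(-0.04, 0.04))

        row = {
            "code": f"F{i:05d}",
            "main_category": cat,
            "subcategory": sub,
            "is_beverage": cat == "beverages",
            ENERGY: energy,
            "protein": protein,
            "fat": fat,
            "carbohydrate": carb,
            "fiber": fiber,
        }
        # Micros: per-gram density scaled to the daily RDI so that a ~500 g
        # meal supplies a plausible fraction of adequacy.
        for n in MAR_MICROS:
            conc = rng.lognormal(mean=np.log(7.5e-4), sigma=0.8)
            row[n] = DAILY_RDI[n] * conc
        # Limit nutrients are scaled against energy so that typical meals
        # sit near (mostly under) dietary-guidance densities — about
        # 1.15 mg sodium per kcal, 10% of energy from added sugars, 9%
        # from saturated fat — and the upper-bound portion stages engage
        # only on the salty/sweet tail of the food space.
        row["saturated_fat"] = fat * rng.uniform(0.06, 0.18)
        salty = cat in ("soups", "snacks_sweets", "mixed_dishes", "condiments_sauces")
        row["sodium"] = energy * rng.lognormal(mean=np.log(0.85 if salty else 0.45), sigma=0.35)
        added = cat in ("snacks_sweets", "beverages", "condiments_sauces")
        added_share = rng.uniform(0.05, 0.13) if added else rng.uniform(0.0, 0.02)
        row["added_sugars"] = added_share * energy / 4.0
        intrinsic = carb * (rng.uniform(0.3, 0.5) if cat == "fruits" else rng.uniform(0.02, 0.12))
        row["total_sugars"] = row["added_sugars"] + intrinsic
        cholesterol_rich = cat in ("protein_foods", "eggs", "dairy", "seafood")
        row["cholesterol"] = rng.lognormal(mean=np.log(0.45), sigma=0.5) if cholesterol_rich else rng.uniform(0.0, 0.05)
        rows.append(row)

    df = pd.DataFrame(rows).set_index("code")
    return FoodCatalog(df, panel)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative recipe for one meal archetype.

    ``category_weights`` is a simplex over catalog main categories;
    ``lambda_items`` is the Poisson mean of (item count - 1);
    ``gram_log_sd`` scales lognormal portion noise; ``zipf_s`` sets food
    popularity decay within a category.
    """

    name: str
    meal_type: str
    category_weights: dict[str, float]
    lambda_items: float = 3.0
    gram_log_sd: float = 0.4
    zipf_s: float = 1.2
    gram_log_medians: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.meal_type not in MEAL_TYPES:
            raise ValueError(f"unknown meal type {self.meal_type!r}")
        total = sum(self.category_weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"category weights must sum to 1, got {total}")
        if self.lambda_items < 0:
            raise ValueError("lambda_items must be >= 0 (item count is 1 + Poisson)")

    def gram_median(self, category: str) -> float:
        if category in self.gram_log_medians:
            return float(np.exp(self.gram_log_medians[category]))
        return _GRAM_MEDIANS.get(category, _DEFAULT_GRAM_MEDIAN)


def default_archetypes(
    catalog: FoodCatalog,
    n_per_type: int = 4,
    seed: int = 0,
    dominant_weight: float = 0.85,
    lambda_items: float = 3.0,
) -> list[ArchetypeSpec]:
    """Well-separated archetypes: one dominant category each.

    Within a meal type, each archetype concentrates ``dominant_weight``
    of its category mass on a single energy-dense plate category
    (profile energy density >= 1.4 kcal/g, so a category-capped portion
    can still carry a meal's energy share), disjoint across the type's
    archetypes; beverages take a common share and the remainder spreads
    thinly over the other categories. Single-category dominance keeps
    each archetype's meal cloud unimodal, which is what "well separated"
    means here — it mirrors the energy-dense plates (cereal bowls,
    sandwiches, pizza) that dominate real meal archetypes. This planted
    structure is what the clustering and generation benchmarks recover.
    """
    rng = np.random.default_rng(seed)
    cats = catalog.categories

    def _profile_energy(c: str) -> float:
        p, f, carb, _ = _MACRO_PROFILES.get(c, _DEFAULT_MACRO_PROFILE)
        return atwater_energy(p, carb, f)

    solid = [
        c for c in cats
        if c != "beverages"
        and _profile_energy(c) >= 1.4
        and _GRAM_MEDIANS.get(c, _DEFAULT_GRAM_MEDIAN) >= 30.0
    ]
    if len(solid) < 2:  # degenerate catalogs: fall back to plate-scale rule
        solid = [
            c for c in cats
            if c != "beverages" and _GRAM_MEDIANS.get(c, _DEFAULT_GRAM_MEDIAN) >= 30.0
        ]
    if len(solid) < 2:
        raise ValueError("need at least 2 plate-scale non-beverage categories")
    specs = []
    for t_idx, meal_type in enumerate(MEAL_TYPES):
        for a in range(n_per_type):
            dom = solid[(a + t_idx * n_per_type) % len(solid)]
            weights = {c: 0.0 for c in cats}
            weights[dom] += dominant_weight
            rest = 1.0 - dominant_weight
            bev_share = 0.4  # beverages common across archetypes
            if "beverages" in weights:
                weights["beverages"] += rest * bev_share
                rest *= 1.0 - bev_share
            others = [c for c in cats if c not in (dom, "beverages")]
            if others:
                spread = rng.dirichlet(np.full(len(others), 2.0))
                for c, w in zip(others, spread):
                    weights[c] += rest * w
            else:
                weights[dom] += rest
            specs.append(
                ArchetypeSpec(
                    name=f"{meal_type}_{dom}",
                    meal_type=meal_type,
                    category_weights=weights,
                    lambda_items=lambda_items,
                )
            )
    return specs


def _zipf_probs(n: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks**-s
    return p / p.sum()


def generate_corpus(
    catalog: FoodCatalog,
    archetypes: list[ArchetypeSpec],
    n_meals: int,
    meal_type_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> MealCorpus:
    """Sample a meal corpus from archetype specs.

    Each meal draws a meal type from ``meal_type_mix``, an archetype
    uniformly among those of that type, an item count 1 + Poisson(lambda),
    then foods by Zipf popularity within weight-sampled categories without
    replacement, with lognormal gram amounts. The archetype index within
    ``archetypes`` is recorded as ``true_archetype``.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    if len(archetypes) < 2:
        raise ValueError("need at least 2 archetypes")
    if n_meals < 1:
        raise ValueError("n_meals must be >= 1")
    mix = np.asarray(meal_type_mix, dtype=float)
    if mix.shape != (3,) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("meal_type_mix must be a 3-simplex (breakfast, lunch, dinner)")

    rng = np.random.default_rng(seed)
    by_type: dict[str, list[int]] = {t: [] for t in MEAL_TYPES}
    for idx, spec in enumerate(archetypes):
        by_type[spec.meal_type].append(idx)

    # Per-category food lists in code order; Zipf rank = position.
    cat_foods = {
        c: sorted(catalog.df.index[catalog.df["main_category"] == c]) for c in catalog.categories
    }

    rows = []
    for m in range(n_meals):
        meal_type = MEAL_TYPES[rng.choice(3, p=mix)]
        pool = by_type[meal_type]
        if not pool:
            raise ValueError(f"no archetype defined for meal type {meal_type!r}")
        arch_idx = int(pool[rng.integers(len(pool))])
        spec = archetypes[arch_idx]

        n_items = 1 + int(rng.poisson(spec.lambda_items))
        cats = [c for c, w in spec.category_weights.items() if w > 0]
        cat_w = np.array([spec.category_weights[c] for c in cats])
        cat_w = cat_w / cat_w.sum()

        chosen: list[tuple[str, str]] = []
        used: set[str] = set()
        attempts = 0
        while len(chosen) < n_items and attempts < 20 * n_items:
            attempts += 1
            cat = cats[rng.choice(len(cats), p=cat_w)]
            foods = [f for f in cat_foods.get(cat, []) if f not in used]
            if not foods:
                continue
            full = cat_foods[cat]
            probs = _zipf_probs(len(full), spec.zipf_s)
            keep = np.array([f not in used for f in full])
            probs = probs * keep
            probs = probs / probs.sum()
            food = full[rng.choice(len(full), p=probs)]
            used.add(food)
            chosen.append((food, cat))
        if not chosen:  # pathological weight/catalog mismatch
            cat = catalog.df["main_category"].iloc[0]
            chosen = [(catalog.codes[0], cat)]

        meal_id = f"M{m:06d}"
        for food, cat in chosen:
            median = spec.gram_median(cat)
            grams = float(np.exp(rng.normal(np.log(median), spec.gram_log_sd)))
            rows.append(
                {
                    "meal_id": meal_id,
                    "meal_type": meal_type,
                    "food_code": food,
                    "grams": round(grams, 2),
                    "true_archetype": arch_idx,
                }
            )
    return MealCorpus(pd.DataFrame(rows))


def generate_serving_table(catalog: FoodCatalog, seed: int = 0) -> pd.Series:
    """Canonical serving size (g) per food: category-typical with jitter."""
    rng = np.random.default_rng(seed)
    medians = catalog.df["main_category"].map(lambda c: _GRAM_MEDIANS.get(c, _DEFAULT_GRAM_MEDIAN))
    jitter = rng.lognormal(0.0, 0.15, size=len(catalog))
    s = pd.Series(medians.to_numpy(dtype=float) * jitter, index=catalog.df.index, name="serving_g")
    return s.round(1)


def generate_pricing_config(catalog: FoodCatalog, seed: int = 0) -> dict:
    """Portion-based pricing config: per-category portion size and price.

    Matches the restaurant-style model: grams-per-portion and
    price-per-portion per named category, per-item caps, a cross-item cap
    of one soup bowl per meal, a generic side default (150 g, $3), and a
    fixed $2 per-meal overhead.
    """
    rng = np.random.default_rng(seed)
    categories = {}
    for cat in catalog.categories:
        gpp = _GRAM_MEDIANS.get(cat, _DEFAULT_GRAM_MEDIAN)
        price = float(np.round(rng.uniform(1.5, 8.0), 2))
        categories[cat] = {
            "grams_per_portion": float(gpp),
            "price_per_portion": price,
            "item_cap": 3.0,
        }
    if "soups" in categories:
        categories["soups"]["item_cap"] = 1.0
    return {
        "categories": categories,
        "cross_item_caps": {"soups": 1.0},
        "generic_default": {"grams_per_portion": 150.0, "price_per_portion": 3.0, "item_cap": 3.0},
        "overhead": 2.0,
    }
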