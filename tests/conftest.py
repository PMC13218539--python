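"""Shared fixtures: small synthetic catalogs/corpora generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mealforge.containers import FoodCatalog, MealCorpus
from mealforge.nutrients import DEFAULT_PANEL, ENERGY
from mealforge.synth import default_archetypes, generate_catalog, generate_corpus

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_catalog() -> FoodCatalog:
    return generate_catalog(n_foods=60, n_categories=6, seed=101)


@pytest.fixture(scope="session")
def small_corpus(small_catalog) -> MealCorpus:
    specs = default_archetypes(small_catalog, n_per_type=2, seed=102)
    return generate_corpus(small_catalog, specs, n_meals=300, seed=103)


@pytest.fixture(scope="session")
def bench_catalog() -> FoodCatalog:
    """The synthetic benchmark catalog: 200 foods, 10 categories."""
    return generate_catalog(n_foods=200, n_categories=10, seed=5)


@pytest.fixture(scope="session")
def bench_corpus(bench_catalog) -> MealCorpus:
    """The synthetic benchmark corpus: 2,000 meals, 4 archetypes/meal type."""
    specs = default_archetypes(bench_catalog, n_per_type=4, seed=6)
    return generate_corpus(bench_catalog, specs, n_meals=2000, seed=7)


def tiny_catalog(rows: list[dict]) -> FoodCatalog:
    """Hand-built catalog; unspecified nutrient densities default to 0."""
    full = []
    for r in rows:
        base = {n: 0.0 for n in DEFAULT_PANEL.names}
        base.update(
            {"main_category": "misc", "subcategory": "misc/1", "is_beverage": False, ENERGY: 0.0}
        )
        base.update(r)
        full.append(base)
    df = pd.DataFrame(full).set_index("code")
    return FoodCatalog(df)


def corpus_from_items(meals: list[tuple[str, str, list[tuple[str, float]]]]) -> MealCorpus:
    """(meal_id, meal_type, [(food, grams), ...]) triples -> MealCorpus."""
    rows = [
        {"meal_id": mid, "meal_type": mt, "food_code": f, "grams": g, "true_archetype": -1}
        for mid, mt, items in meals
        for f, g in items
    ]
    return MealCorpus(pd.DataFrame(rows))
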