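"""On-disk formats: catalog/corpus CSV, config YAML.

Catalog CSV is wide (one row per food); corpus CSV is long (one row per
meal item). Both are diff-able, language-neutral, and round-trip exactly
through pandas default float formatting.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from mealforge.containers import FoodCatalog, MealCorpus
from mealforge.nutrients import DEFAULT_PANEL, ENERGY, NutrientPanel


class ParseError(ValueError):
    """Malformed on-disk row; message names the offending line."""


def write_catalog(catalog: FoodCatalog, path) -> None:
    catalog.df.to_csv(path, index_label="code")


def read_catalog(path, panel: NutrientPanel = DEFAULT_PANEL) -> FoodCatalog:
    df = pd.read_csv(path, dtype={"code": str})
    if "code" not in df.columns:
        raise ParseError(f"{path}: missing 'code' column")
    numeric = [ENERGY, *panel.names]
    for col in numeric:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric {col!r} at data line {bad[0] + 2}")
        df[col] = coerced
    df["is_beverage"] = df["is_beverage"].astype(bool)
    return FoodCatalog(df.set_index("code"), panel)


def write_corpus(corpus: MealCorpus, path) -> None:
    cols = ["meal_id", "meal_type", "food_code", "grams", "true_archetype"]
    corpus.df[cols].to_csv(path, index=False)


def read_corpus(path, catalog: FoodCatalog | None = None) -> MealCorpus:
    df = pd.read_csv(path, dtype={"meal_id": str, "food_code": str})
    for col in ("meal_id", "meal_type", "food_code", "grams"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    grams = pd.to_numeric(df["grams"], errors="coerce")
    bad = df.index[grams.isna()]
    if len(bad):
        raise ParseError(f"{path}: non-numeric grams at data line {bad[0] + 2}")
    nonpos = df.index[grams.to_numpy() <= 0]
    if len(nonpos):
        raise ParseError(f"{path}: grams <= 0 at data line {nonpos[0] + 2}")
    df["grams"] = grams
    if "true_archetype" in df.columns:
        df["true_archetype"] = df["true_archetype"].fillna(-1).astype(int)
    corpus = MealCorpus(df)
    if catalog is not None:
        unknown = set(df["food_code"]) - set(catalog.df.index)
        if unknown:
            raise ParseError(f"{path}: unknown food codes {sorted(unknown)[:5]}")
    return corpus


def write_servings(servings: pd.Series, path) -> None:
    servings.rename("serving_g").to_csv(path, index_label="code")


def read_servings(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"code": str})
    s = df.set_index("code")["serving_g"].astype(float)
    if (s.to_numpy() <= 0).any():
        raise ParseError(f"{path}: serving sizes must be positive")
    return s


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pathlib.Path):
        return str(obj)
    return obj
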