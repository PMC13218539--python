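"""Few-item meal substitutions on a nutrition-vs-cost frontier.

For each generated meal we search similar real meals (item-set Jaccard
blended with nutrient-composition cosine, requiring comparable energy and
item count) plus same-category single-item swaps; k counts the items
replaced. Nutrition gain is the percent reduction in mean absolute
deviation from per-meal RDI targets; cost uses a portion-based
restaurant-style pricing model (grams-per-portion and price-per-portion
per category, per-item and cross-item caps such as at most one soup bowl
per meal, a generic side default of 150 g / $3, and a fixed $2 per-meal
overhead). Winners maximise gain + theta * savings%, subject to optional
budget and no-cost-increase constraints; the frontier over a theta grid
is summarised by its knee (maximum perpendicular distance from the
endpoint chord).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mealforge.containers import FoodCatalog, MealCorpus
from mealforge.portioning import MealTargets, rdi_deviation

Items = list[tuple[str, float]]


# ---------------------------------------------------------------- pricing


@dataclass
class PricingModel:
    """Portion-based pricing: per-category portion size and price.

    ``dialect`` is "portion" (restaurant-style) or "per100g" (grocery
    sensitivity dialect: price per 100 g, no portion caps).
    """

    categories: dict[str, dict] = field(default_factory=dict)
    cross_item_caps: dict[str, float] = field(default_factory=dict)
    generic_default: dict = field(
        default_factory=lambda: {"grams_per_portion": 150.0, "price_per_portion": 3.0, "item_cap": 3.0}
    )
    overhead: float = 2.0
    dialect: str = "portion"

    @classmethod
    def from_config(cls, cfg: dict) -> "PricingModel":
        return cls(
            categories=cfg.get("categories", {}),
            cross_item_caps=cfg.get("cross_item_caps", {}),
            generic_default=cfg.get(
                "generic_default",
                {"grams_per_portion": 150.0, "price_per_portion": 3.0, "item_cap": 3.0},
            ),
            overhead=float(cfg.get("overhead", 2.0)),
            dialect=cfg.get("dialect", "portion"),
        )


def meal_cost(items: Items, catalog: FoodCatalog, pricing: PricingModel) -> float:
    """Cost of a meal in USD under the pricing model.

    Portions per item are grams / grams-per-portion capped at the item
    cap; cross-item caps limit total billed portions of a named category;
    the per-meal overhead is added exactly once.
    """
    cross_remaining = {c: float(cap) for c, cap in pricing.cross_item_caps.items()}
    cost = pricing.overhead
    for code, grams in items:
        if grams < 0:
            raise ValueError(f"negative grams for {code}")
        cat = str(catalog.df.loc[code, "main_category"]) if code in catalog else ""
        entry = pricing.categories.get(cat, pricing.generic_default)
        if pricing.dialect == "per100g":
            cost += entry.get("price_per_100g", entry["price_per_portion"] / entry["grams_per_portion"] * 100.0) * grams / 100.0
            continue
        portions = min(grams / entry["grams_per_portion"], float(entry.get("item_cap", np.inf)))
        if cat in cross_remaining:
            billed = min(portions, cross_remaining[cat])
            cross_remaining[cat] -= billed
        else:
            billed = portions
        cost += billed * entry["price_per_portion"]
    return float(cost)


# ------------------------------------------------------------- candidates


def hop_count(items_a, items_b) -> int:
    """k = max(|A - B|, |B - A|): replacements plus unpaired adds/removes."""
    a, b = set(items_a), set(items_b)
    return max(len(a - b), len(b - a))


@dataclass
class SubstitutionCandidate:
    items: Items
    source: str  # "real:<meal_id>" or "swap:<removed>-><added>"
    k: int
    gain_pct: float = np.nan
    cost: float = np.nan
    cost_delta: float = np.nan
    similarity: float = np.nan


@dataclass
class TradeoffPolicy:
    theta: float = 0.0  # emphasis on cost savings
    budget: float | None = None  # max candidate cost (USD)
    no_cost_increase: bool = False
    max_hops: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta < 0:
            raise ValueError("theta must be finite and >= 0")


def _composition_vector(items: Items, catalog: FoodCatalog) -> np.ndarray:
    dens = catalog.density_matrix()
    v = np.zeros(dens.shape[1])
    for code, grams in items:
        v += grams * dens.loc[code].to_numpy()
    scale = dens.to_numpy().mean(axis=0)
    scale[scale == 0] = 1.0
    return v / scale


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def nutrition_gain(
    orig_items: Items, cand_items: Items, catalog: FoodCatalog, targets: MealTargets
) -> float | None:
    """Percent reduction in mean |RDI deviation|; None when the original
    deviation is zero (gain undefined)."""
    dev_o = _deviation(orig_items, catalog, targets)
    if dev_o == 0:
        return None
    dev_c = _deviation(cand_items, catalog, targets)
    return 100.0 * (dev_o - dev_c) / dev_o


def _deviation(items: Items, catalog: FoodCatalog, targets: MealTargets) -> float:
    dens = catalog.density_matrix()
    totals = np.zeros(dens.shape[1])
    for code, grams in items:
        totals += grams * dens.loc[code].to_numpy()
    s = pd.Series(totals, index=dens.columns)
    dev, _ = rdi_deviation(s, targets)
    return dev


def find_candidates(
    gen_items: Items,
    meal_type: str,
    real: MealCorpus,
    catalog: FoodCatalog,
    targets: MealTargets,
    pricing: PricingModel,
    alpha: float = 0.5,
    energy_tol: float = 0.15,
    count_tol: int = 1,
    max_hops: int | None = None,
    include_swaps: bool = True,
) -> list[SubstitutionCandidate]:
    """Candidate substitutions: similar real meals + single-item swaps.

    Real meals are scored alpha * Jaccard(item sets) + (1 - alpha) *
    cosine(nutrient composition) and filtered to comparable energy
    (|dE|/E <= energy_tol) and item count (|dn| <= count_tol); identity
    (k = 0) is excluded. Single-item swaps replace one item with another
    food of the same main category present in the real corpus, moving the
    removed item's grams onto the added food.
    """
    gen_set = {c for c, _ in gen_items}
    gen_vec = _composition_vector(gen_items, catalog)
    dens_e = catalog.energy_density()
    gen_energy = sum(g * dens_e[c] for c, g in gen_items)
    gen_cost = meal_cost(gen_items, catalog, pricing)
    dev_o = _deviation(gen_items, catalog, targets)
    if dev_o == 0:
        return []

    out: list[SubstitutionCandidate] = []

    sub = real.by_meal_type(meal_type)
    for mid in sub.meal_ids:
        items = sub.items(mid)
        k = hop_count(gen_set, {c for c, _ in items})
        if k == 0:
            continue
        if max_hops is not None and k > max_hops:
            continue
        if abs(len(items) - len(gen_items)) > count_tol:
            continue
        energy = sum(g * dens_e[c] for c, g in items)
        if gen_energy > 0 and abs(energy - gen_energy) / gen_energy > energy_tol:
            continue
        sim = alpha * _jaccard(gen_set, {c for c, _ in items}) + (1 - alpha) * _cosine(
            gen_vec, _composition_vector(items, catalog)
        )
        out.append(_scored(gen_items, items, f"real:{mid}", k, sim, catalog, targets,
                           pricing, gen_cost, dev_o))

    if include_swaps:
        real_foods = set(real.df["food_code"])
        for i, (code, grams) in enumerate(gen_items):
            cat = catalog.df.loc[code, "main_category"]
            same_cat = [
                f for f in sorted(real_foods)
                if f != code and f not in gen_set and f in catalog
                and catalog.df.loc[f, "main_category"] == cat
            ]
            for new in same_cat:
                items = list(gen_items)
                items[i] = (new, grams)
                energy = sum(g * dens_e[c] for c, g in items)
                if gen_energy > 0 and abs(energy - gen_energy) / gen_energy > energy_tol:
                    continue
                sim = alpha * _jaccard(gen_set, {c for c, _ in items}) + (1 - alpha) * _cosine(
                    gen_vec, _composition_vector(items, catalog)
                )
                out.append(_scored(gen_items, items, f"swap:{code}->{new}", 1, sim,
                                   catalog, targets, pricing, gen_cost, dev_o))
    return out


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if (a | b) else 0.0


def _scored(gen_items, items, source, k, sim, catalog, targets, pricing, gen_cost, dev_o):
    dev_c = _deviation(items, catalog, targets)
    cost = meal_cost(items, catalog, pricing)
    return SubstitutionCandidate(
        items=items,
        source=source,
        k=k,
        gain_pct=100.0 * (dev_o - dev_c) / dev_o,
        cost=cost,
        cost_delta=cost - gen_cost,
        similarity=sim,
    )


# ---------------------------------------------------------------- select


def select(
    candidates: list[SubstitutionCandidate],
    policy: TradeoffPolicy,
    original_cost: float,
) -> SubstitutionCandidate | None:
    """Winner = argmax of gain + theta * savings%, after policy filters.

    Ties break to fewer hops, then lower cost, then source string.
    """
    pool = []
    for c in candidates:
        if policy.max_hops is not None and c.k > policy.max_hops:
            continue
        if policy.no_cost_increase and c.cost_delta > 0:
            continue
        if policy.budget is not None and c.cost > policy.budget:
            continue
        savings_pct = 100.0 * (original_cost - c.cost) / original_cost if original_cost > 0 else 0.0
        score = c.gain_pct + policy.theta * savings_pct
        pool.append((score, -c.k, -c.cost, c))
    if not pool:
        return None
    pool.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3].source))
    return pool[0][3]


# --------------------------------------------------------------- frontier


def knee_point(savings: np.ndarray, gains: np.ndarray) -> int:
    """Index of maximum perpendicular distance from the endpoint chord."""
    pts = np.stack([savings, gains], axis=1)
    if len(pts) < 3:
        return 0
    a, b = pts[0], pts[-1]
    chord = b - a
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0
    rel = pts - a
    d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
    return int(np.argmax(d))


def frontier(
    gen_meals: list[tuple[Items, str]],
    real: MealCorpus,
    catalog: FoodCatalog,
    targets_by_type: dict[str, MealTargets],
    pricing: PricingModel,
    theta_grid,
    max_hops: int | None = 3,
    n_boot: int = 1000,
    seed: int = 0,
    **search_kw,
) -> dict:
    """Population cost-benefit curve over a theta grid, with knee point.

    Returns per-theta medians of nutrition gain and cost savings (with
    percentile bootstrap CIs), the feasibility fraction, and the knee.
    """
    theta_grid = list(theta_grid)
    if not theta_grid:
        raise ValueError("theta grid must be nonempty")
    rng = np.random.default_rng(seed)

    cached = []
    n_feasible = 0
    for items, meal_type in gen_meals:
        cands = find_candidates(
            items, meal_type, real, catalog, targets_by_type[meal_type], pricing,
            max_hops=max_hops, **search_kw,
        )
        cost0 = meal_cost(items, catalog, pricing)
        if cands:
            n_feasible += 1
        cached.append((cands, cost0))

    rows = []
    for theta in theta_grid:
        policy = TradeoffPolicy(theta=theta, max_hops=max_hops)
        gains, savings = [], []
        for cands, cost0 in cached:
            w = select(cands, policy, cost0)
            if w is None:
                continue
            gains.append(w.gain_pct)
            savings.append(100.0 * (cost0 - w.cost) / cost0 if cost0 > 0 else 0.0)
        row = {"theta": float(theta), "n_winners": len(gains)}
        if gains:
            g, s = np.asarray(gains), np.asarray(savings)
            row["median_gain"] = float(np.median(g))
            row["median_savings"] = float(np.median(s))
            if len(g) >= 2:
                bg = [np.median(g[rng.integers(0, g.size, g.size)]) for _ in range(n_boot)]
                bs = [np.median(s[rng.integers(0, s.size, s.size)]) for _ in range(n_boot)]
                row["gain_ci"] = [float(np.quantile(bg, 0.025)), float(np.quantile(bg, 0.975))]
                row["savings_ci"] = [float(np.quantile(bs, 0.025)), float(np.quantile(bs, 0.975))]
        rows.append(row)

    curve = pd.DataFrame(rows)
    valid = curve.dropna(subset=["median_gain"]) if "median_gain" in curve else curve.iloc[:0]
    result = {
        "curve": curve,
        "feasibility_fraction": n_feasible / len(gen_meals) if gen_meals else 0.0,
    }
    if len(valid):
        idx = knee_point(valid["median_savings"].to_numpy(), valid["median_gain"].to_numpy())
        result["knee"] = valid.iloc[idx].to_dict()
    return result


# ------------------------------------------------------------ transitions


def transition_matrix(
    winners: list[tuple[Items, SubstitutionCandidate]], catalog: FoodCatalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category transition probabilities from winning substitutions.

    Removed and added items are paired by nutrient-density cosine
    similarity (greedy, deterministic); unpaired items enter the
    marginals as net adds/removes. Rows (removed category) are normalised
    to sum to 1. Returns (matrix, marginals).
    """
    dens = catalog.density_matrix()
    counts: dict[tuple[str, str], int] = {}
    net: dict[str, dict[str, int]] = {}

    def _cat(code: str) -> str:
        return str(catalog.df.loc[code, "main_category"])

    any_swap = False
    for orig_items, winner in winners:
        a = {c for c, _ in orig_items}
        b = {c for c, _ in winner.items}
        removed = sorted(a - b)
        added = sorted(b - a)
        if removed or added:
            any_swap = True
        pairs = []
        rem, add = list(removed), list(added)
        while rem and add:
            best = None
            for r in rem:
                for d in add:
                    s = _cosine(dens.loc[r].to_numpy(), dens.loc[d].to_numpy())
                    key = (-s, r, d)
                    if best is None or key < best[0]:
                        best = (key, r, d)
            _, r, d = best
            pairs.append((r, d))
            rem.remove(r)
            add.remove(d)
        for r, d in pairs:
            key = (_cat(r), _cat(d))
            counts[key] = counts.get(key, 0) + 1
        for r in rem:
            net.setdefault(_cat(r), {"removes": 0, "adds": 0})["removes"] += 1
        for d in add:
            net.setdefault(_cat(d), {"removes": 0, "adds": 0})["adds"] += 1

    if not any_swap:
        raise ValueError("no winner contains a swap")
    cats = sorted({c for k in counts for c in k} | set(net))
    mat = pd.DataFrame(0.0, index=cats, columns=cats)
    for (r, d), n in counts.items():
        mat.loc[r, d] = n
    sums = mat.sum(axis=1)
    mat = mat.div(sums.where(sums > 0, 1.0), axis=0)
    marg = pd.DataFrame(
        [{"category": c, **net.get(c, {"removes": 0, "adds": 0})} for c in cats]
    ).set_index("category")
    return mat, marg
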