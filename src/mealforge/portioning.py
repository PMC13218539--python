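"""Portion assignment: grams for a generated food set.

A meal's nutrient targets are its meal-type share (breakfast 25%, lunch
35%, dinner 40%) of the daily RDI/limit table and of a 2,000 kcal energy
target. Portions are initialised from canonical serving sizes with small
jitter and refined by projected gradient descent on a signed log2
deviation objective with asymmetric penalties (under-consumption of
protein, fiber and micronutrients weighs more; over-consumption of
sodium, saturated fat and sugars weighs more). Six constraint stages are
then applied in a fixed order:

1. per-item minimum 5 g;
2. per-item and per-category gram caps;
3. energy retargeting (uniform rescale of non-capped items, 1% tolerance);
4. upper-bound-only caps on sodium, total sugars and saturated fat
   (largest contributors scaled down, never up);
5. beverage gram cap and beverage energy fraction <= 25% of meal kcal;
6. total-grams cap 900 g with rebalancing, then one re-run of stage 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mealforge.containers import FoodCatalog
from mealforge.nutrients import DEFAULT_PANEL, ENERGY, NutrientPanel
from mealforge.synth import DAILY_LIMITS, DAILY_RDI

MEAL_SHARES = {"breakfast": 0.25, "lunch": 0.35, "dinner": 0.40}

# upper-bound-only portion caps: sodium, (added) sugars, saturated fat
LIMIT_STAGE_NUTRIENTS = ("sodium", "added_sugars", "saturated_fat")


@dataclass
class RDITable:
    """Daily adequacy references, upper limits, and the energy target."""

    rdi: dict[str, float] = field(default_factory=lambda: dict(DAILY_RDI))
    limits: dict[str, float] = field(default_factory=lambda: dict(DAILY_LIMITS))
    daily_energy: float = 2000.0
    panel: NutrientPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        for n, v in {**self.rdi, **self.limits, "energy": self.daily_energy}.items():
            if v <= 0:
                raise ValueError(f"reference value for {n} must be positive, got {v}")
        missing = [m for m in self.panel.micros if m not in self.rdi]
        if missing:
            raise ValueError(f"MAR micronutrients without an RDI: {missing}")
        for n in LIMIT_STAGE_NUTRIENTS:
            if n not in self.limits:
                raise ValueError(f"limit nutrient {n} missing an upper limit")


@dataclass
class MealTargets:
    """Per-meal targets: meal-type share of the daily references."""

    meal_type: str
    share: float
    adequacy: dict[str, float]
    limits: dict[str, float]
    energy: float

    @property
    def nutrients(self) -> list[str]:
        return list(self.adequacy) + list(self.limits)

    def vector(self, names: list[str]) -> np.ndarray:
        merged = {**self.adequacy, **self.limits}
        return np.array([merged[n] for n in names])


def per_meal_targets(rdi: RDITable, meal_type: str) -> MealTargets:
    if meal_type not in MEAL_SHARES:
        raise ValueError(f"unknown meal type {meal_type!r}; expected {sorted(MEAL_SHARES)}")
    share = MEAL_SHARES[meal_type]
    return MealTargets(
        meal_type=meal_type,
        share=share,
        adequacy={n: share * v for n, v in rdi.rdi.items()},
        limits={n: share * v for n, v in rdi.limits.items()},
        energy=share * rdi.daily_energy,
    )


@dataclass
class PortionConfig:
    under_weight: float = 2.0  # under-consumption of protein/fiber/micros
    over_weight: float = 2.0  # over-consumption of sodium/SFA/sugars
    base_weight: float = 1.0
    min_g: float = 5.0
    per_item_cap: float = 400.0
    per_category_cap: float = 500.0
    beverage_cap_g: float = 500.0
    total_cap_g: float = 900.0
    beverage_kcal_frac: float = 0.25
    energy_tol: float = 0.01
    step: float = 2.0
    max_iter: int = 300
    rel_tol: float = 1e-5
    jitter_frac: float = 0.1
    default_serving_g: float = 100.0


def init_portions(
    foods: list[str],
    serving_table: pd.Series | None,
    jitter_frac: float = 0.1,
    seed: int = 0,
    default_serving_g: float = 100.0,
    min_g: float = 5.0,
) -> np.ndarray:
    """Serving sizes with uniform multiplicative jitter, floored at 5 g."""
    rng = np.random.default_rng(seed)
    if serving_table is None:
        serving_table = pd.Series(dtype=float)
    base = np.array([float(serving_table.get(f, default_serving_g)) for f in foods])
    jitter = rng.uniform(-jitter_frac, jitter_frac, size=len(foods))
    return np.maximum(min_g, base * (1.0 + jitter))


def _weights_vector(targets: MealTargets, intake: np.ndarray, names: list[str],
                    config: PortionConfig) -> np.ndarray:
    t = targets.vector(names)
    w = np.full(len(names), config.base_weight)
    for i, n in enumerate(names):
        if n in targets.limits:
            if intake[i] > t[i]:
                w[i] = config.over_weight
        else:
            if intake[i] < t[i]:
                w[i] = config.under_weight
    return w


def objective(
    grams: np.ndarray,
    densities: np.ndarray,
    targets: MealTargets,
    names: list[str],
    config: PortionConfig | None = None,
    eps: float = 1e-6,
) -> float:
    """Sum of asymmetric-weighted |log2(intake / target)| over nutrients.

    ``densities`` is foods x nutrients aligned with ``names``.
    """
    config = config or PortionConfig()
    intake = np.maximum(grams @ densities, eps)
    t = targets.vector(names)
    w = _weights_vector(targets, intake, names, config)
    return float(np.sum(w * np.abs(np.log2(intake / t))))


def _objective_grad(grams, densities, targets, names, config, eps=1e-6):
    intake = np.maximum(grams @ densities, eps)
    t = targets.vector(names)
    w = _weights_vector(targets, intake, names, config)
    sign = np.sign(np.log2(intake / t))
    d_intake = w * sign / (intake * np.log(2.0))
    return densities @ d_intake


def refine_portions(
    grams: np.ndarray,
    densities: np.ndarray,
    targets: MealTargets,
    names: list[str],
    config: PortionConfig | None = None,
) -> np.ndarray:
    """Projected gradient descent on the signed log2 objective.

    Iterates with the analytic gradient of the piecewise objective and an
    adaptive step (grown on improvement, halved on failure), projecting
    onto [min_g, per_item_cap]; keeps the best iterate and stops when the
    step collapses or the relative improvement falls below rel_tol. The
    result never scores worse than the (projected) initialisation.
    """
    config = config or PortionConfig()
    grams = np.clip(grams, config.min_g, config.per_item_cap)
    best = grams.copy()
    best_obj = objective(best, densities, targets, names, config)
    step = config.step
    for _ in range(config.max_iter):
        grad = _objective_grad(best, densities, targets, names, config)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-14 or step < 1e-6:
            break
        trial = np.clip(best - step * grad / gnorm * max(np.abs(best).max(), 1.0),
                        config.min_g, config.per_item_cap)
        obj = objective(trial, densities, targets, names, config)
        if obj < best_obj - config.rel_tol * max(best_obj, 1e-12):
            best, best_obj = trial, obj
            step *= 1.3
        else:
            if obj < best_obj:
                best, best_obj = trial, obj
            step *= 0.5
    return best


@dataclass
class PortionSolution:
    food_codes: list[str]
    grams: np.ndarray
    objective_value: float
    nutrient_totals: pd.Series
    meal_energy: float
    constraint_report: list[dict]
    feasible: bool
    violated_stages: list[str]

    def to_items(self) -> list[tuple[str, float]]:
        return list(zip(self.food_codes, map(float, self.grams)))


def _nutrient_arrays(catalog: FoodCatalog, foods: list[str], targets: MealTargets):
    # objective/limit nutrients only: adequacy targets + upper limits
    names = [n for n in catalog.panel.names if n in set(targets.nutrients)]
    dens = catalog.df.loc[foods, names].to_numpy(dtype=float)
    energy = catalog.df.loc[foods, ENERGY].to_numpy(dtype=float)
    bev = catalog.df.loc[foods, "is_beverage"].to_numpy(dtype=bool)
    cats = catalog.df.loc[foods, "main_category"].to_numpy()
    return names, dens, energy, bev, cats


def optimize_portions(
    foods: list[str],
    catalog: FoodCatalog,
    targets: MealTargets,
    config: PortionConfig | None = None,
    serving_table: pd.Series | None = None,
    seed: int = 0,
) -> PortionSolution:
    """Gradient refinement plus the six-stage constraint pipeline."""
    if len(foods) == 0:
        raise ValueError("need at least one food")
    config = config or PortionConfig()
    names, dens, energy_d, bev, cats = _nutrient_arrays(catalog, foods, targets)

    grams = init_portions(
        foods, serving_table, config.jitter_frac, seed, config.default_serving_g, config.min_g
    )
    grams = refine_portions(grams, dens, targets, names, config)

    report: list[dict] = []

    def log(stage, applied, detail=""):
        report.append({"stage": stage, "applied": bool(applied), "detail": detail})

    # (stage 1) per-item minimum
    low = grams < config.min_g
    grams = np.maximum(grams, config.min_g)
    log("min_grams", low.any())

    # (stage 2) per-item and per-category caps
    high = grams > config.per_item_cap
    grams = np.minimum(grams, config.per_item_cap)
    applied = bool(high.any())
    for cat in np.unique(cats):
        m = cats == cat
        total = grams[m].sum()
        if total > config.per_category_cap:
            scale = config.per_category_cap / total
            grams[m] = np.maximum(config.min_g, grams[m] * scale)
            applied = True
    log("item_category_caps", applied)

    def retarget_energy(g: np.ndarray) -> tuple[np.ndarray, bool]:
        """Uniformly rescale non-capped items to hit the energy target."""
        g = g.copy()
        fixed = np.zeros(len(g), dtype=bool)
        for _ in range(8):
            e = float(g @ energy_d)
            if abs(e - targets.energy) / targets.energy <= config.energy_tol:
                return g, True
            free = ~fixed
            e_free = float(g[free] @ energy_d[free])
            if e_free <= 0 or not free.any():
                return g, False
            scale = (targets.energy - (e - e_free)) / e_free
            if scale <= 0:
                return g, False
            new = g[free] * scale
            over = new > config.per_item_cap
            under = new < config.min_g
            new = np.clip(new, config.min_g, config.per_item_cap)
            g[free] = new
            idx = np.flatnonzero(free)
            fixed[idx[over | under]] = True
        e = float(g @ energy_d)
        return g, abs(e - targets.energy) / targets.energy <= config.energy_tol

    # (stage 3) energy retargeting
    grams, energy_ok = retarget_energy(grams)
    log("energy_retarget", True, f"energy={float(grams @ energy_d):.1f}")

    # (stage 4) upper-bound-only caps on sodium, sugars, SFA (scale down only)
    applied = False
    for nut in LIMIT_STAGE_NUTRIENTS:
        j = names.index(nut)
        limit = targets.limits[nut]
        for _ in range(len(foods)):
            intake = float(grams @ dens[:, j])
            if intake <= limit:
                break
            contrib = grams * dens[:, j]
            movable = grams > config.min_g
            if not movable.any():
                break
            i = int(np.argmax(np.where(movable, contrib, -np.inf)))
            excess = intake - limit
            reducible = (grams[i] - config.min_g) * dens[i, j]
            if dens[i, j] <= 0:
                break
            cut = min(excess / dens[i, j], grams[i] - config.min_g)
            grams[i] -= cut
            applied = True
            if reducible >= excess:
                break
    log("limit_caps", applied)

    # (stage 5) beverage gram cap and beverage energy fraction
    applied = False
    if bev.any():
        bev_total = grams[bev].sum()
        if bev_total > config.beverage_cap_g:
            grams[bev] = np.maximum(config.min_g, grams[bev] * config.beverage_cap_g / bev_total)
            applied = True
        bev_kcal = float(grams[bev] @ energy_d[bev])
        solid_kcal = float(grams[~bev] @ energy_d[~bev])
        frac = config.beverage_kcal_frac
        if bev_kcal > frac / (1 - frac) * solid_kcal + 1e-12:
            # solve bev' = frac * (solid + bev')
            target_bev = frac / (1.0 - frac) * solid_kcal
            scale = target_bev / bev_kcal if bev_kcal > 0 else 1.0
            grams[bev] = np.maximum(config.min_g, grams[bev] * scale)
            applied = True
    log("beverage", applied)

    # (stage 6) soft total-grams cap with rebalancing
    applied = False
    total = grams.sum()
    if total > config.total_cap_g:
        at_min = grams <= config.min_g
        free_total = grams[~at_min].sum()
        budget = config.total_cap_g - grams[at_min].sum()
        if free_total > 0 and budget > 0:
            grams[~at_min] = np.maximum(config.min_g, grams[~at_min] * budget / free_total)
        applied = True
        grams, energy_ok = retarget_energy(grams)
        # the re-run of stage 3 must not break the cap: only allow it to
        # keep the total at or under the cap
        if grams.sum() > config.total_cap_g:
            grams *= config.total_cap_g / grams.sum()
            grams = np.maximum(config.min_g, grams)
            energy_ok = abs(float(grams @ energy_d) - targets.energy) / targets.energy <= config.energy_tol
    log("total_cap", applied)

    meal_energy = float(grams @ energy_d)
    bev_kcal = float(grams[bev] @ energy_d[bev]) if bev.any() else 0.0
    violated = []
    if abs(meal_energy - targets.energy) / targets.energy > config.energy_tol:
        violated.append("energy_retarget")
    if bev.any() and meal_energy > 0 and bev_kcal / meal_energy > config.beverage_kcal_frac + 1e-9:
        violated.append("beverage")
    if grams.sum() > config.total_cap_g + 1e-9:
        violated.append("total_cap")
    for nut in LIMIT_STAGE_NUTRIENTS:
        j = names.index(nut)
        if float(grams @ dens[:, j]) > targets.limits[nut] * (1 + 1e-9):
            violated.append(f"limit:{nut}")

    full_dens = catalog.df.loc[foods, list(catalog.panel.names)].to_numpy(dtype=float)
    totals = pd.Series(grams @ full_dens, index=list(catalog.panel.names))
    totals[ENERGY] = meal_energy
    totals["total_grams"] = float(grams.sum())
    return PortionSolution(
        food_codes=list(foods),
        grams=grams,
        objective_value=objective(grams, dens, targets, names, config),
        nutrient_totals=totals,
        meal_energy=meal_energy,
        constraint_report=report,
        feasible=not violated,
        violated_stages=violated,
    )


def rdi_deviation(
    totals: pd.Series,
    targets: MealTargets,
    scope: list[str] | None = None,
) -> tuple[float, pd.Series]:
    """Mean absolute fractional deviation from per-meal targets.

    Adequacy nutrients contribute |intake - target| / target; limit
    nutrients contribute max(0, intake - limit) / limit (no credit for
    being under a limit). Returns (mean, per-nutrient series).
    """
    scope = scope or targets.nutrients
    per = {}
    for n in scope:
        if n in targets.limits:
            lim = targets.limits[n]
            per[n] = max(0.0, float(totals[n]) - lim) / lim
        else:
            t = targets.adequacy[n]
            per[n] = abs(float(totals[n]) - t) / t
    s = pd.Series(per)
    return float(s.mean()), s
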