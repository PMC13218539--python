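"""Corpus cleaning and compression.

Five operations, applied in practice in this order: food-code
harmonization against a discontinuation mapping, presence binarization per
meal type, Local Outlier Factor removal of extreme meal compositions
(contamination 0.3% by default), nutrient-aware prototype aggregation via
greedy facility location (weighted mass coverage >= 90%, nutrient fidelity
<= 7%, assignment similarity floor 0.70), and a bootstrap confidence
interval filter that drops foods whose presence cannot be bounded away
from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from mealforge.containers import FoodCatalog, MealCorpus

HARMONIZE_ACTIONS = ("expanded", "consolidated", "renumbered", "dropped", "revised")
_REPLACE_ACTIONS = ("expanded", "consolidated", "renumbered")


@dataclass
class CodeMapping:
    """Food-code discontinuation table.

    Rows of (old code, action, new code). Expanded / consolidated /
    renumbered codes are replaced by their most recent code; dropped and
    revised codes are kept unchanged.
    """

    df: pd.DataFrame  # columns: old_code, action, new_code (nullable)

    def __post_init__(self) -> None:
        bad = set(self.df["action"]) - set(HARMONIZE_ACTIONS)
        if bad:
            raise ValueError(f"unknown mapping actions: {sorted(bad)}")
        needs_new = self.df["action"].isin(_REPLACE_ACTIONS)
        if self.df.loc[needs_new, "new_code"].isna().any():
            raise ValueError("expanded/consolidated/renumbered rows need a new code")

    def closure(self) -> dict[str, str]:
        """Transitive closure old -> final code; raises on cycles."""
        step = {
            str(r.old_code): str(r.new_code)
            for r in self.df.itertuples()
            if r.action in _REPLACE_ACTIONS
        }
        final: dict[str, str] = {}
        for start in step:
            seen = [start]
            cur = start
            while cur in step:
                cur = step[cur]
                if cur in seen:
                    cycle = seen[seen.index(cur):] + [cur]
                    raise ValueError(f"code mapping cycle: {' -> '.join(cycle)}")
                seen.append(cur)
            final[start] = cur
        return final


def harmonize_codes(corpus: MealCorpus, mapping: CodeMapping) -> MealCorpus:
    """Replace discontinued codes by their most recent code, merging grams.

    Duplicate foods created by consolidation are merged by summing grams;
    dropped/revised codes are retained unchanged. Idempotent after the
    transitive closure.
    """
    closure = mapping.closure()
    df = corpus.df.copy()
    df["food_code"] = df["food_code"].map(lambda c: closure.get(c, c))
    merged = (
        df.groupby(["meal_id", "meal_type", "food_code"], sort=False, as_index=False)
        .agg(grams=("grams", "sum"), true_archetype=("true_archetype", "first"))
    )
    return MealCorpus(merged[["meal_id", "meal_type", "food_code", "grams", "true_archetype"]])


@dataclass
class PresenceMatrix:
    """Binary meals x foods matrix for one meal type."""

    matrix: np.ndarray
    meal_ids: list[str]
    food_codes: list[str]
    meal_type: str

    def __post_init__(self) -> None:
        vals = np.unique(self.matrix)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        if (self.matrix.sum(axis=1) < 1).any():
            raise ValueError("every meal must contain at least one food")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.meal_ids, columns=self.food_codes)


def binarize(corpus: MealCorpus) -> dict[str, PresenceMatrix]:
    """Presence/absence matrices, one per meal type present in the corpus."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    out = {}
    for meal_type in sorted(corpus.df["meal_type"].unique()):
        sub = corpus.by_meal_type(meal_type)
        foods = sorted(sub.df["food_code"].unique())
        wide = sub.df.pivot_table(
            index="meal_id", columns="food_code", values="grams", aggfunc="sum", fill_value=0.0
        ).reindex(columns=foods, fill_value=0.0)
        wide = wide.loc[sub.meal_ids]
        out[meal_type] = PresenceMatrix(
            (wide.to_numpy() > 0).astype(np.int8), list(wide.index), foods, meal_type
        )
    return out


def lof_filter(
    features: pd.DataFrame, contamination: float = 0.003, n_neighbors: int = 20
) -> tuple[list[str], list[str]]:
    """Remove the round(contamination * n) most extreme meals by LOF score.

    ``features`` is a meals x features frame (typically the hybrid features
    of :func:`mealforge.archetypes.extract_features`). Returns
    (retained ids, removed ids); removal is ranked by the negative outlier
    factor, most extreme first, ties broken by meal id.
    """
    if not 0 < contamination < 0.5:
        raise ValueError(f"contamination must be in (0, 0.5), got {contamination}")
    n = len(features)
    if n < 20:
        raise ValueError("need at least 20 meals for LOF filtering")
    n_remove = int(round(contamination * n))
    if n_remove == 0:
        return list(features.index), []
    lof = LocalOutlierFactor(n_neighbors=min(n_neighbors, n - 1))
    lof.fit(features.to_numpy(dtype=float))
    scores = pd.Series(lof.negative_outlier_factor_, index=features.index)
    order = scores.sort_values(kind="stable").index  # most negative = most extreme
    # stable sort + index order gives deterministic ties
    removed = list(order[:n_remove])
    removed_set = set(removed)
    retained = [m for m in features.index if m not in removed_set]
    return retained, removed


@dataclass
class PrototypeMap:
    """Food -> prototype assignment with per-subcategory quality stats.

    ``assignment`` maps every catalog food to a prototype food (prototypes
    map to themselves); ``similarity`` is the nutrient-space cosine
    similarity of each food to its prototype (1.0 for self);
    ``stats`` has per-subcategory coverage (weighted mass fraction at or
    above the similarity floor), fidelity (weighted MARE of the
    prototype-reconstructed nutrient totals) and prototype counts.
    """

    assignment: pd.Series
    similarity: pd.Series
    weights: pd.Series
    stats: pd.DataFrame
    sim_floor: float

    @property
    def prototypes(self) -> list[str]:
        return sorted(set(self.assignment))

    def apply(self, corpus: MealCorpus) -> MealCorpus:
        """Map corpus foods onto their prototypes, merging grams."""
        df = corpus.df.copy()
        df["food_code"] = df["food_code"].map(lambda c: self.assignment.get(c, c))
        merged = (
            df.groupby(["meal_id", "meal_type", "food_code"], sort=False, as_index=False)
            .agg(grams=("grams", "sum"), true_archetype=("true_archetype", "first"))
        )
        return MealCorpus(merged)


def _normalised_densities(catalog: FoodCatalog) -> pd.DataFrame:
    """Densities scaled per nutrient by catalog mean, so cosine weights
    nutrients comparably despite unit differences (mg vs g)."""
    dens = catalog.density_matrix()
    scale = dens.mean(axis=0).replace(0.0, 1.0)
    return dens / scale


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    norms[norms == 0] = 1.0
    u = x / norms[:, None]
    return np.clip(u @ u.T, -1.0, 1.0)


def aggregate_prototypes(
    catalog: FoodCatalog,
    corpus: MealCorpus,
    coverage_min: float = 0.90,
    fidelity_max: float = 0.07,
    sim_floor: float = 0.70,
) -> PrototypeMap:
    """Greedy facility-location prototype selection per subcategory.

    Food weights are total grams consumed in the corpus. Within each
    subcategory, prototypes are added greedily (largest weighted-coverage
    gain first, ties broken by food code) until weighted mass coverage at
    similarity >= ``sim_floor`` reaches ``coverage_min`` AND the weighted
    mean absolute relative error of the prototype-reconstructed nutrient
    totals falls to ``fidelity_max`` or below. Foods whose similarity to
    every selected prototype stays under the floor become their own
    prototypes, so the thresholds are always attainable.
    """
    totals = corpus.df.groupby("food_code")["grams"].sum()
    weights = totals.reindex(catalog.codes).fillna(0.0)
    dens_norm = _normalised_densities(catalog)

    assignment: dict[str, str] = {}
    similarity: dict[str, float] = {}
    stats_rows = []

    for sub in catalog.subcategories:
        codes = sorted(catalog.df.index[catalog.df["subcategory"] == sub])
        w = weights.loc[codes].to_numpy(dtype=float)
        x = dens_norm.loc[codes].to_numpy(dtype=float)
        dens_raw = catalog.density_matrix().loc[codes].to_numpy(dtype=float)
        sim = _cosine_matrix(x)
        n = len(codes)
        w_total = w.sum()

        selected: list[int] = []

        def _assign(sel: list[int]) -> tuple[np.ndarray, np.ndarray]:
            """nearest selected prototype and its similarity, per food."""
            if not sel:
                return np.full(n, -1), np.full(n, -np.inf)
            s = sim[:, sel]
            best = np.argmax(s, axis=1)
            return np.asarray(sel)[best], s[np.arange(n), best]

        def _coverage(best_sim: np.ndarray, proto: np.ndarray) -> float:
            if w_total == 0:
                return 1.0
            covered = (best_sim >= sim_floor) | (proto == np.arange(n))
            return float(w[covered].sum() / w_total)

        def _fidelity(proto: np.ndarray, best_sim: np.ndarray) -> float:
            """Weighted MARE between original and reconstructed totals."""
            if w_total == 0:
                return 0.0
            eff = np.where((best_sim >= sim_floor) & (proto >= 0), proto, np.arange(n))
            orig = w @ dens_raw
            recon = w @ dens_raw[eff]
            denom = np.where(np.abs(orig) > 1e-12, np.abs(orig), 1.0)
            return float(np.mean(np.abs(recon - orig) / denom))

        while True:
            proto, best_sim = _assign(selected)
            cov = _coverage(best_sim, proto)
            fid = _fidelity(proto, best_sim)
            if (cov >= coverage_min and fid <= fidelity_max) or len(selected) == n:
                break
            # candidate adding step: maximise coverage gain, then fidelity drop
            best_j, best_key = None, None
            remaining = [j for j in range(n) if j not in selected]
            for j in remaining:
                trial = selected + [j]
                p, bs = _assign(trial)
                key = (-_coverage(bs, p), _fidelity(p, bs), codes[j])
                if best_key is None or key < best_key:
                    best_key, best_j = key, j
            selected.append(best_j)

        proto, best_sim = _assign(selected)
        arange = np.arange(n)
        is_self = proto == arange
        final_proto = np.where((best_sim >= sim_floor) & ~is_self, proto, arange)
        final_proto = np.where(is_self, arange, final_proto)
        for i in range(n):
            assignment[codes[i]] = codes[int(final_proto[i])]
            similarity[codes[i]] = 1.0 if final_proto[i] == i else float(sim[i, final_proto[i]])

        # Recompute reported stats on the final assignment.
        eff = final_proto
        orig = w @ dens_raw
        recon = w @ dens_raw[eff]
        denom = np.where(np.abs(orig) > 1e-12, np.abs(orig), 1.0)
        fid_final = float(np.mean(np.abs(recon - orig) / denom)) if w_total > 0 else 0.0
        covered = (eff == arange) | (sim[arange, eff] >= sim_floor)
        cov_final = float(w[covered].sum() / w_total) if w_total > 0 else 1.0
        stats_rows.append(
            {
                "subcategory": sub,
                "n_foods": n,
                "n_prototypes": len(set(eff.tolist())),
                "coverage": cov_final,
                "fidelity": fid_final,
            }
        )

    return PrototypeMap(
        assignment=pd.Series(assignment).sort_index(),
        similarity=pd.Series(similarity).sort_index(),
        weights=weights,
        stats=pd.DataFrame(stats_rows).set_index("subcategory"),
        sim_floor=sim_floor,
    )


def bootstrap_ingredient_filter(
    pm: PresenceMatrix,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    threshold: float = 0.0,
) -> list[str]:
    """Retain foods whose bootstrap CI for mean presence clears ``threshold``.

    For each food, a percentile bootstrap CI of its mean presence across
    meals is formed from ``n_boot`` row resamples; the food is removed iff
    the CI lower bound is <= ``threshold`` (default 0: rare foods the
    bootstrap cannot bound away from zero).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    x = pm.matrix.astype(float)
    n = x.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    mult = np.zeros((n_boot, n))
    for b in range(n_boot):
        mult[b] = np.bincount(idx[b], minlength=n)
    means = (mult @ x) / n
    lower = np.quantile(means, (1.0 - level) / 2.0, axis=0)
    return [f for f, lo in zip(pm.food_codes, lower) if lo > threshold]
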