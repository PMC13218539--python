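"""Meal-quality metrics and the generated-vs-real evaluation harness.

Five per-meal metrics:

* MER (mean excess ratio): mean of intake / upper-limit over the limit
  nutrients — quantifies average proportional excess;
* MAR (mean adequacy ratio): mean over the 11 micronutrients of
  NAR = min(1, intake / RDI);
* AMDR composite: fraction of the three macronutrients whose share of
  energy falls inside its acceptable range (protein 10-35%, fat 20-35%,
  carbohydrate 45-65%, bounds inclusive);
* diversity: Hill number over food-group gram proportions (order 1 =
  exponential Shannon by default);
* energy density: kcal per gram.

Plus percentile-bootstrap confidence intervals (1,000 resamples by
default), cluster-level generated-vs-real comparisons with BH/FDR control,
and a stratified 5-fold cross-validation harness for the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from mealforge.containers import FoodCatalog, MealCorpus
from mealforge.nutrients import DEFAULT_PANEL, ENERGY
from mealforge.portioning import MealTargets, RDITable, per_meal_targets, rdi_deviation

AMDR_BOUNDS = {"protein": (10.0, 35.0), "fat": (20.0, 35.0), "carbohydrate": (45.0, 65.0)}

MER_NUTRIENTS = ("sodium", "saturated_fat", "added_sugars")


def mer(intakes: dict[str, float], limits: dict[str, float]) -> float:
    """Mean Excess Ratio: (1/K) sum of intake_k / limit_k."""
    if not limits:
        raise ValueError("need at least one limit nutrient")
    ratios = []
    for k, lim in limits.items():
        if lim <= 0:
            raise ValueError(f"limit for {k} must be positive")
        ratios.append(intakes[k] / lim)
    return float(np.mean(ratios))


def mar(intakes: dict[str, float], rdis: dict[str, float], panel=DEFAULT_PANEL) -> float:
    """Mean Adequacy Ratio over the 11 MAR micronutrients, NAR capped at 1."""
    nars = []
    for n in panel.micros:
        if n not in intakes:
            raise ValueError(f"missing micronutrient intake: {n}")
        if n not in rdis:
            raise ValueError(f"missing RDI: {n}")
        nars.append(min(1.0, intakes[n] / rdis[n]))
    return float(np.mean(nars))


def amdr_composite(energy_shares: dict[str, float], bounds=None) -> float:
    """Fraction of macros whose percent-of-energy lies in its AMDR range."""
    bounds = bounds or AMDR_BOUNDS
    ok = [1.0 if lo <= energy_shares[m] <= hi else 0.0 for m, (lo, hi) in bounds.items()]
    return float(np.mean(ok))


def hill_diversity(proportions, q: float = 1.0) -> float:
    """Hill number (sum p_i^q)^(1/(1-q)); Shannon exponential at q = 1."""
    p = np.asarray(list(proportions), dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {p.sum()}")
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    if abs(q - 1.0) < 1e-12:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def energy_density(total_kcal: float, total_grams: float) -> float:
    if total_grams <= 0:
        raise ValueError("total grams must be positive")
    return float(total_kcal / total_grams)


def bootstrap_ci(
    values, statistic=np.mean, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float, float]:
    """Percentile bootstrap CI: (point estimate, lower, upper)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    stats = np.array([statistic(x[rng.integers(0, x.size, x.size)]) for _ in range(n_boot)])
    alpha = (1.0 - level) / 2.0
    return float(statistic(x)), float(np.quantile(stats, alpha)), float(np.quantile(stats, 1 - alpha))


# ------------------------------------------------------------- per meal


def macro_energy_shares(totals: pd.Series) -> dict[str, float]:
    """Percent of energy from protein / fat / carbohydrate (Atwater)."""
    kcal = {"protein": 4.0 * totals["protein"], "fat": 9.0 * totals["fat"],
            "carbohydrate": 4.0 * totals["carbohydrate"]}
    total = sum(kcal.values())
    if total <= 0:
        return {m: 0.0 for m in kcal}
    return {m: 100.0 * v / total for m, v in kcal.items()}


def evaluate_meals(
    corpus: MealCorpus,
    catalog: FoodCatalog,
    rdi: RDITable,
    mer_nutrients=MER_NUTRIENTS,
    diversity_q: float = 1.0,
) -> pd.DataFrame:
    """Per-meal metric report: MER, MAR, AMDR, diversity, energy density,
    RDI deviation. Diversity groups are main food categories, proportions
    by grams."""
    totals = corpus.nutrient_totals(catalog)
    types = corpus.meal_types()
    targets = {t: per_meal_targets(rdi, t) for t in types.unique()}

    cat_g = corpus.df.merge(
        catalog.df[["main_category"]], left_on="food_code", right_index=True
    ).pivot_table(index="meal_id", columns="main_category", values="grams",
                  aggfunc="sum", fill_value=0.0)
    cat_g = cat_g.reindex(totals.index, fill_value=0.0)

    rows = []
    for mid in totals.index:
        tt = totals.loc[mid]
        tgt: MealTargets = targets[types[mid]]
        lim = {n: tgt.limits[n] for n in mer_nutrients}
        props = cat_g.loc[mid].to_numpy()
        props = props / props.sum()
        dev, _ = rdi_deviation(tt, tgt)
        rows.append(
            {
                "meal_id": mid,
                "meal_type": types[mid],
                "mer": mer({n: tt[n] for n in lim}, lim),
                "mar": mar({n: tt[n] for n in tgt.adequacy}, tgt.adequacy),
                "amdr": amdr_composite(macro_energy_shares(tt)),
                "diversity": hill_diversity(props, q=diversity_q),
                "energy_density": energy_density(tt[ENERGY], tt["total_grams"]),
                "rdi_deviation": dev,
                "energy_kcal": float(tt[ENERGY]),
            }
        )
    return pd.DataFrame(rows).set_index("meal_id")


# ------------------------------------------------- generated vs real


def compare_generated_vs_real(
    gen: pd.DataFrame,
    real: pd.DataFrame,
    value: str = "rdi_deviation",
    cluster_col: str = "cluster",
    n_boot: int = 1000,
    level: float = 0.95,
    fdr_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Cluster-level generated-vs-real comparison.

    Per cluster: bootstrap CI of the difference in median ``value``
    (generated - real); an improvement is counted when the CI upper bound
    is below zero; percent reduction of the cluster-level median is
    100 * (real - gen) / real (not applicable when the real median is 0).
    The overall summary is the median percent reduction across clusters
    with a bootstrap CI over clusters; per-cluster bootstrap p-values are
    BH-adjusted at ``fdr_alpha``.
    """
    rng = np.random.default_rng(seed)
    common = sorted(set(gen[cluster_col]) & set(real[cluster_col]))
    skipped = sorted(set(gen[cluster_col]) ^ set(real[cluster_col]))
    if skipped:
        import warnings

        warnings.warn(f"clusters present in only one set skipped: {skipped}")
    alpha = (1.0 - level) / 2.0
    rows = []
    for c in common:
        g = gen.loc[gen[cluster_col] == c, value].to_numpy(dtype=float)
        r = real.loc[real[cluster_col] == c, value].to_numpy(dtype=float)
        diffs = np.array(
            [
                np.median(g[rng.integers(0, g.size, g.size)])
                - np.median(r[rng.integers(0, r.size, r.size)])
                for _ in range(n_boot)
            ]
        )
        lo, hi = np.quantile(diffs, alpha), np.quantile(diffs, 1 - alpha)
        med_g, med_r = float(np.median(g)), float(np.median(r))
        p = 2.0 * min((diffs >= 0).mean(), (diffs <= 0).mean())
        rows.append(
            {
                "cluster": c,
                "median_gen": med_g,
                "median_real": med_r,
                "diff_ci_low": float(lo),
                "diff_ci_high": float(hi),
                "improved": bool(hi < 0),
                "pct_reduction": (100.0 * (med_r - med_g) / med_r) if med_r > 0 else np.nan,
                "p_boot": min(1.0, float(p) + 1.0 / n_boot),
            }
        )
    per_cluster = pd.DataFrame(rows).set_index("cluster")
    per_cluster["q"] = multipletests(per_cluster["p_boot"], method="fdr_bh")[1]
    per_cluster["significant"] = per_cluster["q"] <= fdr_alpha

    red = per_cluster["pct_reduction"].dropna().to_numpy()
    overall: dict = {"n_clusters": len(common),
                     "frac_improved": float(per_cluster["improved"].mean())}
    if red.size >= 2:
        est, lo, hi = bootstrap_ci(red, np.median, n_boot=n_boot, level=level,
                                   seed=int(rng.integers(2**31)))
        overall.update(median_pct_reduction=est, ci_low=lo, ci_high=hi)
    elif red.size == 1:
        overall["median_pct_reduction"] = float(red[0])
    return {"per_cluster": per_cluster, "overall": overall}


# ------------------------------------------------------- cross-validation


def make_folds(labels: pd.Series, meal_types: pd.Series, k: int = 5, seed: int = 0) -> pd.Series:
    """Stratified fold assignment by (cluster, meal type), round-robin.

    Clusters smaller than k are folded together with the stratum's
    round-robin anyway (every meal still gets a fold).
    """
    rng = np.random.default_rng(seed)
    fold = pd.Series(-1, index=labels.index, dtype=int)
    strata = pd.DataFrame({"c": labels, "t": meal_types.loc[labels.index]})
    start = 0
    for _, grp in strata.groupby(["c", "t"], sort=True):
        ids = grp.index.to_numpy()
        rng.shuffle(ids)
        fold.loc[ids] = (np.arange(len(ids)) + start) % k
        start += len(ids)
    return fold


def crossval_harness(
    corpus: MealCorpus,
    labels: pd.Series,
    config,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """k-fold CV of the generator: train on k-1 folds, score micro-F1 on
    the held-out fold. Stratified by (cluster, meal type); noise meals
    are excluded."""
    from mealforge.generator import MealCVAE, build_training_arrays, micro_f1

    X, cl, mt, foods, ids = build_training_arrays(corpus, labels)
    fold = make_folds(labels[labels != -1], corpus.meal_types(), k=k, seed=seed)
    fold = fold.loc[ids].to_numpy()

    rows = []
    for f in range(k):
        test = fold == f
        train = ~test
        cfg = config.__class__(**{**config.__dict__, "seed": config.seed + f})
        model = MealCVAE(foods, sorted(set(int(c) for c in cl[train])), cfg)
        model.fit(X[train], cl[train], mt[train])
        known = np.isin(cl, list(model.cluster_index)) & test
        f1 = micro_f1(X[known], model.reconstruct(X[known], cl[known], mt[known]))
        rows.append({"fold": f, "n_train": int(train.sum()), "n_test": int(test.sum()),
                     "test_micro_f1": f1})
    return pd.DataFrame(rows)
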