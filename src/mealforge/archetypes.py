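"""Meal-archetype discovery.

Meals are embedded in a hybrid feature space combining (i) nutritional
composition (macro grams, energy, macro energy shares, energy density,
fiber per 1,000 kcal, macro diversity, meal balance, item count, portion
variability) and (ii) categorical food composition (grams per main
category and subcategory), z-scored within meal type. Clustering is
HDBSCAN per meal type followed by a centroid-cosine merge step; clusters
are profiled against their complement with Welch t-tests under
Benjamini-Hochberg control (q <= 0.01, |mean difference| >= 0.15 for
significance, >= 0.20 for "distinctive", Cohen's d reported), and
stability is assessed by subsample-and-recluster ARI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import HDBSCAN
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from mealforge.containers import FoodCatalog, MealCorpus
from mealforge.nutrients import ENERGY

Q_SIGNIFICANT = 0.01
DELTA_SIGNIFICANT = 0.15
DELTA_DISTINCTIVE = 0.20


@dataclass
class HybridFeatures:
    """Z-scored meal embedding (within meal type) plus raw values."""

    frame: pd.DataFrame  # meals x features, z-scored within meal type
    raw: pd.DataFrame  # same shape, pre-standardisation
    meal_types: pd.Series  # meal_id -> meal_type

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def for_type(self, meal_type: str) -> pd.DataFrame:
        return self.frame.loc[self.meal_types[self.meal_types == meal_type].index]


def hill_shannon(p: np.ndarray) -> float:
    """Hill number of order 1 (exponential Shannon) of a simplex vector."""
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(np.exp(-np.sum(p * np.log(p))))


def _gini(p: np.ndarray) -> float:
    """Gini coefficient of a small nonnegative vector (0 = perfectly even)."""
    if p.sum() <= 0:
        return 0.0
    x = np.sort(p)
    n = x.size
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def extract_features(corpus: MealCorpus, catalog: FoodCatalog) -> HybridFeatures:
    """Build the hybrid feature embedding for every meal in the corpus."""
    corpus.validate_against(catalog)
    totals = corpus.nutrient_totals(catalog)
    meal_types = corpus.meal_types()

    energy = totals[ENERGY].to_numpy()
    protein = totals["protein"].to_numpy()
    fat = totals["fat"].to_numpy()
    carb = totals["carbohydrate"].to_numpy()
    fiber = totals["fiber"].to_numpy()
    grams = totals["total_grams"].to_numpy()

    zero_energy = energy <= 0
    if zero_energy.any():
        warnings.warn(f"{zero_energy.sum()} zero-energy meals; ratio features set to 0")
    safe_e = np.where(zero_energy, 1.0, energy)
    macro_kcal = np.stack([4 * protein, 9 * fat, 4 * carb], axis=1)
    macro_e = macro_kcal.sum(axis=1)
    shares = np.divide(
        macro_kcal, np.where(macro_e > 0, macro_e, 1.0)[:, None],
        out=np.zeros_like(macro_kcal), where=macro_e[:, None] > 0,
    )

    feats = pd.DataFrame(index=totals.index)
    feats["energy_kcal"] = energy
    feats["protein_g"] = protein
    feats["fat_g"] = fat
    feats["carbohydrate_g"] = carb
    feats["fiber_g"] = fiber
    feats["total_grams"] = grams
    feats["protein_share"] = np.where(zero_energy, 0.0, shares[:, 0])
    feats["fat_share"] = np.where(zero_energy, 0.0, shares[:, 1])
    feats["carb_share"] = np.where(zero_energy, 0.0, shares[:, 2])
    feats["energy_density"] = np.where(grams > 0, energy / np.where(grams > 0, grams, 1.0), 0.0)
    feats["fiber_per_1000kcal"] = np.where(zero_energy, 0.0, fiber / safe_e * 1000.0)
    feats["macro_diversity"] = [
        0.0 if z else hill_shannon(s) for z, s in zip(zero_energy, shares)
    ]
    # Meal balance: 1 - Gini of macro energy shares (1 = even plate).
    feats["meal_balance"] = [0.0 if z else 1.0 - _gini(s) for z, s in zip(zero_energy, shares)]

    counts = corpus.item_counts()
    feats["item_count"] = counts.reindex(feats.index).to_numpy(dtype=float)
    log_sd = corpus.df.assign(lg=np.log(corpus.df["grams"])).groupby("meal_id", sort=False)["lg"].std()
    feats["portion_variability"] = log_sd.reindex(feats.index).fillna(0.0).to_numpy()

    # Category block: grams per main category and subcategory.
    df = corpus.df.merge(
        catalog.df[["main_category", "subcategory"]], left_on="food_code", right_index=True
    )
    for col, prefix in (("main_category", "cat"), ("subcategory", "sub")):
        g = df.pivot_table(index="meal_id", columns=col, values="grams", aggfunc="sum", fill_value=0.0)
        g = g.reindex(feats.index, fill_value=0.0)
        g.columns = [f"{prefix}:{c}" for c in g.columns]
        feats = feats.join(g)

    z = feats.copy()
    for meal_type in meal_types.unique():
        ids = meal_types[meal_types == meal_type].index
        block = feats.loc[ids]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        # constant columns: tolerance absorbs float noise in the mean
        tiny = sd <= 1e-12 + 1e-9 * mu.abs()
        zb = (block - mu).div(sd.where(~tiny, 1.0), axis=1)
        zb.loc[:, tiny] = 0.0
        z.loc[ids] = zb
    return HybridFeatures(frame=z, raw=feats, meal_types=meal_types)


@dataclass
class ClusterParams:
    """HDBSCAN + merge parameters for one meal type."""

    min_cluster_size: int | None = None  # default max(15, n // 200)
    min_samples: int | None = None  # None: follows min_cluster_size
    cluster_selection_epsilon: float = 0.0
    cluster_selection_method: str = "leaf"  # fine leaves; the merge step re-glues
    merge_threshold: float = 0.95
    reassign_noise: bool = True  # coverage post-processing: noise -> nearest centroid


def _normalise_rows(x: np.ndarray) -> np.ndarray:
    """Bias-augmented row L2 normalisation.

    A constant column at the median row norm is appended before
    normalising, so meals near the z-space origin (e.g. a corpus with a
    single homogeneous pattern) share a common direction instead of
    scattering over the sphere; off-origin archetype clouds keep their
    directional separation.
    """
    norms = np.linalg.norm(x, axis=1)
    c = float(np.median(norms))
    if c <= 0:
        c = 1.0
    xa = np.hstack([x, np.full((len(x), 1), c)])
    return xa / np.linalg.norm(xa, axis=1, keepdims=True)


def _merge_clusters(x: np.ndarray, labels: np.ndarray, threshold: float) -> np.ndarray:
    """Iteratively merge cluster pairs with centroid cosine >= threshold."""
    labels = labels.copy()
    while True:
        ids = sorted(set(labels) - {-1})
        if len(ids) < 2:
            return labels
        cents = np.stack([x[labels == c].mean(axis=0) for c in ids])
        norms = np.linalg.norm(cents, axis=1)
        norms[norms == 0] = 1.0
        u = cents / norms[:, None]
        sim = u @ u.T
        np.fill_diagonal(sim, -np.inf)
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        if sim[i, j] < threshold:
            return labels
        keep, drop = sorted((ids[i], ids[j]))
        labels[labels == drop] = keep


def cluster_meals(
    features: HybridFeatures,
    params: dict[str, ClusterParams] | None = None,
) -> pd.Series:
    """HDBSCAN labels per meal type with post-processing; -1 marks noise.

    Density clustering runs on the row-L2-normalised z-features (a
    cosine-like embedding that discounts overall meal size), followed by
    two post-processing steps: merging of cluster pairs whose centroids
    exceed the cosine merge threshold, and — for coverage — reassignment
    of noise points to their nearest cluster centroid (disable via
    ``reassign_noise``). Cluster ids are globally unique across meal
    types (offset per type).
    """
    params = params or {}
    labels = pd.Series(-1, index=features.frame.index, dtype=int, name="cluster")
    offset = 0
    for meal_type in sorted(features.meal_types.unique()):
        block = features.for_type(meal_type)
        p = params.get(meal_type, ClusterParams())
        mcs = p.min_cluster_size or max(15, len(block) // 200)
        if len(block) < 10 * mcs:
            mcs = max(5, len(block) // 10)
        x = block.to_numpy(dtype=float)
        xn = _normalise_rows(x)
        hdb = HDBSCAN(
            min_cluster_size=mcs,
            min_samples=p.min_samples,
            cluster_selection_epsilon=p.cluster_selection_epsilon,
            cluster_selection_method=p.cluster_selection_method,
        )
        raw = hdb.fit_predict(xn)
        if (raw == -1).all():
            # a homogeneous meal type is one cluster, which the default
            # selection cannot return; retry allowing a single cluster
            retry = HDBSCAN(
                min_cluster_size=mcs,
                min_samples=p.min_samples,
                cluster_selection_epsilon=p.cluster_selection_epsilon,
                allow_single_cluster=True,
            )
            raw = retry.fit_predict(xn)
        if (raw == -1).all():
            raise RuntimeError(
                f"all {meal_type} meals labelled noise; lower min_cluster_size "
                f"(currently {mcs}) or cluster_selection_epsilon"
            )
        merged = _merge_clusters(xn, raw, p.merge_threshold)
        if p.reassign_noise and (merged == -1).any():
            ids = sorted(set(merged) - {-1})
            cents = np.stack([xn[merged == c].mean(axis=0) for c in ids])
            noise = merged == -1
            d2 = ((xn[noise][:, None, :] - cents[None]) ** 2).sum(axis=-1)
            merged[noise] = np.asarray(ids)[np.argmin(d2, axis=1)]
        # compact ids and offset across meal types
        ids = sorted(set(merged) - {-1})
        remap = {c: offset + k for k, c in enumerate(ids)}
        labels.loc[block.index] = [remap.get(c, -1) for c in merged]
        offset += len(ids)
    return labels


@dataclass
class ClusterProfile:
    """Statistical contrast of one cluster vs its meal-type complement."""

    cluster_id: int
    meal_type: str
    n_meals: int
    table: pd.DataFrame = field(repr=False)  # per feature: means, delta, p, q, d, flags
    unstable: bool = False

    @property
    def significant_features(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def distinctive_features(self) -> list[str]:
        return list(self.table.index[self.table["distinctive"]])


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with pooled standard deviation."""
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        return 0.0
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def profile_clusters(features: HybridFeatures, labels: pd.Series) -> list[ClusterProfile]:
    """Per-cluster feature profiles with BH-corrected Welch t-tests.

    The complement is the set of other meals of the same meal type
    (noise included). BH runs jointly across all cluster x feature tests.
    """
    ids = sorted(set(labels) - {-1})
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters (excluding noise) to profile")

    records = []  # (cluster, feature, delta, p, d, n, meal_type)
    for cid in ids:
        members = labels.index[labels == cid]
        meal_type = features.meal_types[members[0]]
        type_ids = features.meal_types[features.meal_types == meal_type].index
        comp = type_ids.difference(members)
        xblk = features.frame.loc[members]
        yblk = features.frame.loc[comp]
        for feat in features.feature_names:
            x = xblk[feat].to_numpy()
            y = yblk[feat].to_numpy()
            delta = float(x.mean() - (y.mean() if len(y) else 0.0))
            if len(members) < 3 or len(comp) < 3 or (x.var() == 0 and y.var() == 0):
                p = 1.0
            else:
                p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
                if np.isnan(p):
                    p = 1.0
            records.append((cid, meal_type, feat, len(members), x.mean(),
                            y.mean() if len(y) else 0.0, delta, p, cohens_d(x, y)))

    rec = pd.DataFrame(
        records,
        columns=["cluster", "meal_type", "feature", "n", "cluster_mean",
                 "complement_mean", "delta", "p", "d"],
    )
    testable = rec["p"] < 1.0  # size-<3 clusters get tests skipped (p=1, q=1)
    rec["q"] = 1.0
    if testable.any():
        rec.loc[testable, "q"] = multipletests(rec.loc[testable, "p"], method="fdr_bh")[1]
    rec["significant"] = (rec["q"] <= Q_SIGNIFICANT) & (rec["delta"].abs() >= DELTA_SIGNIFICANT)
    rec["distinctive"] = rec["delta"].abs() >= DELTA_DISTINCTIVE

    profiles = []
    for cid in ids:
        sub = rec[rec["cluster"] == cid].set_index("feature")
        profiles.append(
            ClusterProfile(
                cluster_id=int(cid),
                meal_type=str(sub["meal_type"].iloc[0]),
                n_meals=int(sub["n"].iloc[0]),
                table=sub.drop(columns=["cluster", "meal_type", "n"]),
                unstable=bool(sub["n"].iloc[0] < 3),
            )
        )
    return profiles


def stability_ari(
    features: HybridFeatures,
    baseline: pd.Series,
    params: dict[str, ClusterParams] | None = None,
    n_subsamples: int = 20,
    frac: float = 0.8,
    seed: int = 0,
) -> dict:
    """Subsample-and-recluster stability vs baseline labels.

    Returns median ARI, a percentile 95% interval over subsamples, the raw
    per-subsample values, and the same restricted to meals assigned to a
    cluster (non-noise) in both labelings.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(features.frame.index)
    aris, aris_nn = [], []
    for _ in range(n_subsamples):
        take = rng.choice(len(ids), size=int(frac * len(ids)), replace=False)
        sub_ids = ids[np.sort(take)]
        sub_feats = HybridFeatures(
            frame=features.frame.loc[sub_ids],
            raw=features.raw.loc[sub_ids],
            meal_types=features.meal_types.loc[sub_ids],
        )
        new = cluster_meals(sub_feats, params)
        base = baseline.loc[sub_ids]
        aris.append(adjusted_rand_score(base, new))
        mask = (base != -1) & (new != -1)
        if mask.sum() > 1:
            aris_nn.append(adjusted_rand_score(base[mask], new[mask]))
    aris = np.asarray(aris)
    out = {
        "median": float(np.median(aris)),
        "ci_low": float(np.quantile(aris, 0.025)),
        "ci_high": float(np.quantile(aris, 0.975)),
        "values": aris.tolist(),
    }
    if aris_nn:
        out["median_non_noise"] = float(np.median(aris_nn))
    return out
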