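"""End-to-end orchestration: synth -> preprocess -> cluster -> train ->
sample -> portion -> evaluate -> substitute, from one config.

Each stage gets a deterministic seed derived by hashing (global seed,
stage name), so stage-level reproducibility survives reordering or
toggling of other stages. Every artifact directory carries a provenance
file naming the config hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from mealforge import io as mio
from mealforge import synth
from mealforge.archetypes import cluster_meals, extract_features, profile_clusters, stability_ari
from mealforge.containers import MEAL_TYPES, FoodCatalog, MealCorpus
from mealforge.generator import CVAEConfig, train_cvae
from mealforge.metrics import compare_generated_vs_real, evaluate_meals
from mealforge.portioning import (
    MEAL_SHARES,
    PortionConfig,
    RDITable,
    optimize_portions,
    per_meal_targets,
)
from mealforge.preprocess import aggregate_prototypes, binarize, bootstrap_ingredient_filter, lof_filter
from mealforge.substitution import PricingModel, frontier

log = logging.getLogger("mealforge")

ALL_STAGES = ("synth", "preprocess", "cluster", "train", "sample", "portion", "evaluate", "substitute")


@dataclass
class RunConfig:
    out_dir: str = "mealforge_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # synth
    n_foods: int = 200
    n_categories: int = 10
    archetypes_per_type: int = 4
    n_meals: int = 2000
    # preprocess
    contamination: float = 0.003
    bootstrap_n: int = 200
    # cluster
    stability_subsamples: int = 0  # 0 disables the stability stage
    # train / sample
    cvae: dict = field(default_factory=dict)
    n_generated_per_pair: int = 20
    # portion
    portion: dict = field(default_factory=dict)
    # substitute
    theta_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    max_hops: int = 3
    n_substitution_meals: int = 50
    frontier_boot: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = mio.read_yaml(path) or {}
        return cls(**d)

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    report: dict = {"config_hash": cfg_hash, "stages": {}}
    state: dict = {}

    stage_fns = {
        "synth": _stage_synth,
        "preprocess": _stage_preprocess,
        "cluster": _stage_cluster,
        "train": _stage_train,
        "sample": _stage_sample,
        "portion": _stage_portion,
        "evaluate": _stage_evaluate,
        "substitute": _stage_substitute,
    }
    failed = False
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if failed:
            report["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        t0 = time.time()
        try:
            summary = stage_fns[stage](config, state, out)
            summary["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            log.exception("stage %s failed", stage)
            summary = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            failed = True
        summary["elapsed_s"] = round(time.time() - t0, 2)
        report["stages"][stage] = summary
        log.info("stage %-10s %s (%.1fs)", stage, summary["status"], summary["elapsed_s"])

    (out / "provenance.json").write_text(json.dumps({"config_hash": cfg_hash}))
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.generic,)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ------------------------------------------------------------------ stages


def _stage_synth(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    seed = stage_seed(config.seed, "synth")
    catalog = synth.generate_catalog(config.n_foods, config.n_categories, seed)
    specs = synth.default_archetypes(catalog, config.archetypes_per_type, seed + 1)
    corpus = synth.generate_corpus(catalog, specs, config.n_meals, seed=seed + 2)
    servings = synth.generate_serving_table(catalog, seed + 3)
    pricing = synth.generate_pricing_config(catalog, seed + 4)
    mio.write_catalog(catalog, out / "catalog.csv")
    mio.write_corpus(corpus, out / "meals.csv")
    mio.write_servings(servings, out / "servings.csv")
    mio.write_yaml(pricing, out / "pricing.yaml")
    state.update(catalog=catalog, corpus=corpus, servings=servings,
                 pricing=PricingModel.from_config(pricing), archetypes=specs)
    return {"n_foods": len(catalog), "n_meals": len(corpus), "n_archetypes": len(specs)}


def _stage_preprocess(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    seed = stage_seed(config.seed, "preprocess")
    corpus, catalog = state["corpus"], state["catalog"]
    feats = extract_features(corpus, catalog)
    removed_all = []
    retained = []
    for meal_type in sorted(corpus.df["meal_type"].unique()):
        block = feats.for_type(meal_type)
        keep, removed = lof_filter(block, config.contamination)
        retained.extend(keep)
        removed_all.extend(removed)
    clean = corpus.subset(retained)

    proto = aggregate_prototypes(catalog, clean)
    clean = proto.apply(clean)

    kept_foods = set()
    for meal_type, pm in binarize(clean).items():
        kept_foods |= set(
            bootstrap_ingredient_filter(pm, n_boot=config.bootstrap_n, seed=seed)
        )
    df = clean.df[clean.df["food_code"].isin(kept_foods)]
    clean = MealCorpus(df.reset_index(drop=True))

    mio.write_corpus(clean, out / "meals.clean.csv")
    proto.assignment.rename("prototype").to_csv(out / "prototype_map.csv", index_label="code")
    state["clean_corpus"] = clean
    state["prototype_map"] = proto
    return {
        "n_meals_removed_lof": len(removed_all),
        "n_prototypes": len(set(proto.assignment)),
        "n_foods_retained": len(kept_foods),
        "n_meals_clean": len(clean),
        "min_coverage": float(proto.stats["coverage"].min()),
        "max_fidelity": float(proto.stats["fidelity"].max()),
    }


def _stage_cluster(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    corpus, catalog = state["clean_corpus"], state["catalog"]
    feats = extract_features(corpus, catalog)
    labels = cluster_meals(feats)
    profiles = profile_clusters(feats, labels)
    labels.rename("cluster").to_csv(out / "labels.csv", index_label="meal_id")
    prof_json = [
        {
            "cluster": p.cluster_id,
            "meal_type": p.meal_type,
            "n_meals": p.n_meals,
            "distinctive": p.distinctive_features[:10],
        }
        for p in profiles
    ]
    (out / "profiles.json").write_text(json.dumps(prof_json, indent=2))
    summary = {
        "n_clusters": int(len(set(labels) - {-1})),
        "noise_fraction": float((labels == -1).mean()),
    }
    if config.stability_subsamples > 0:
        stab = stability_ari(
            feats, labels, n_subsamples=config.stability_subsamples,
            seed=stage_seed(config.seed, "stability"),
        )
        (out / "stability.json").write_text(json.dumps(stab))
        summary["stability_median_ari"] = stab["median"]
    state["features"] = feats
    state["labels"] = labels
    return summary


def _stage_train(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    cfg = CVAEConfig(**{"seed": stage_seed(config.seed, "train"), **config.cvae})
    model, history, rep = train_cvae(state["clean_corpus"], state["labels"], cfg)
    history.to_csv(out / "train_history.csv", index=False)
    state["model"] = model
    return {k: (round(v, 4) if isinstance(v, float) else v) for k, v in rep.items()}


def _stage_sample(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    seed = stage_seed(config.seed, "sample")
    model = state["model"]
    rows = []
    i = 0
    for (cluster, mt_id) in sorted(model.pair_stats):
        meal_type = MEAL_TYPES[mt_id]
        cluster_arg = cluster if model.config.conditioning else 0
        for foods in model.sample_meals(cluster_arg, meal_type, config.n_generated_per_pair,
                                        seed=seed + i):
            rows.append({"meal_id": f"G{i:06d}", "meal_type": meal_type,
                         "cluster": cluster, "foods": foods})
            i += 1
    state["generated"] = rows
    pd.DataFrame(
        [
            {"meal_id": r["meal_id"], "meal_type": r["meal_type"],
             "cluster": r["cluster"], "food_code": f}
            for r in rows for f in r["foods"]
        ]
    ).to_csv(out / "gen_meals.csv", index=False)
    return {"n_generated": len(rows)}


def _stage_portion(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    seed = stage_seed(config.seed, "portion")
    catalog, servings = state["catalog"], state["servings"]
    rdi = RDITable()
    pcfg = PortionConfig(**config.portion)
    rows, solutions = [], []
    n_feasible = 0
    for i, r in enumerate(state["generated"]):
        targets = per_meal_targets(rdi, r["meal_type"])
        sol = optimize_portions(r["foods"], catalog, targets, pcfg, servings, seed=seed + i)
        n_feasible += sol.feasible
        solutions.append({**r, "solution": sol})
        for f, g in sol.to_items():
            rows.append({"meal_id": r["meal_id"], "meal_type": r["meal_type"],
                         "cluster": r["cluster"], "food_code": f, "grams": round(g, 2)})
    pd.DataFrame(rows).to_csv(out / "portions.csv", index=False)
    state["portioned"] = solutions
    state["rdi"] = rdi
    return {"n_portioned": len(solutions),
            "feasible_fraction": round(n_feasible / max(len(solutions), 1), 4)}


def _stage_evaluate(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    catalog, rdi = state["catalog"], state["rdi"]
    gen_df = pd.DataFrame(
        [
            {"meal_id": s["meal_id"], "meal_type": s["meal_type"],
             "food_code": f, "grams": g, "true_archetype": -1}
            for s in state["portioned"] for f, g in s["solution"].to_items()
        ]
    )
    gen_corpus = MealCorpus(gen_df)
    gen_rep = evaluate_meals(gen_corpus, catalog, rdi)
    real_rep = evaluate_meals(state["clean_corpus"], catalog, rdi)
    gen_rep["cluster"] = {s["meal_id"]: s["cluster"] for s in state["portioned"]}
    gen_rep["cluster"] = gen_rep.index.map({s["meal_id"]: s["cluster"] for s in state["portioned"]})
    real_rep["cluster"] = state["labels"].reindex(real_rep.index).fillna(-1).astype(int)
    real_rep = real_rep[real_rep["cluster"] != -1]
    comp = compare_generated_vs_real(
        gen_rep, real_rep, n_boot=config.frontier_boot,
        seed=stage_seed(config.seed, "evaluate"),
    )
    gen_rep.to_csv(out / "metrics_generated.csv")
    real_rep.to_csv(out / "metrics_real.csv")
    comp["per_cluster"].to_csv(out / "comparison.csv")
    state["gen_corpus"] = gen_corpus
    return {k: (round(v, 4) if isinstance(v, float) else v) for k, v in comp["overall"].items()}


def _stage_substitute(config: RunConfig, state: dict, out: pathlib.Path) -> dict:
    catalog, rdi = state["catalog"], state["rdi"]
    targets = {t: per_meal_targets(rdi, t) for t in MEAL_SHARES}
    meals = [
        (s["solution"].to_items(), s["meal_type"])
        for s in state["portioned"][: config.n_substitution_meals]
    ]
    result = frontier(
        meals, state["clean_corpus"], catalog, targets, state["pricing"],
        theta_grid=config.theta_grid, max_hops=config.max_hops,
        n_boot=config.frontier_boot, seed=stage_seed(config.seed, "substitute"),
    )
    result["curve"].to_json(out / "frontier.json", orient="records")
    summary = {"feasibility_fraction": round(result["feasibility_fraction"], 4)}
    if "knee" in result:
        summary["knee_theta"] = result["knee"]["theta"]
        summary["knee_gain"] = round(float(result["knee"]["median_gain"]), 3)
        summary["knee_savings"] = round(float(result["knee"]["median_savings"]), 3)
    return summary
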