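"""End-to-end orchestration: generate -> cohort -> features -> train -> evaluate.

``run_pipeline`` executes the five stages from one :class:`RunConfig`,
writes each stage's outputs under the run directory, and returns a
manifest with the seeds, config hash, headline metrics (AUCs, ablation,
conversion-curve summary) and relative output paths.  Per-stage seeds are
derived by hashing the global seed with the stage name, so no stage's
random draw count can perturb another stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import adeval, geofence, io as gio, models, synthetic
from .config import RunConfig, config_hash, derive_seed, to_dict
from .errors import StageError
from .features import LandmarkResolver, build_matrices, fit_selections


def _json_safe(obj):
    """Replace non-finite floats with None so manifests stay strict JSON."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (float, np.floating)) and not np.isfinite(obj):
        return None
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": {},
        "metrics": {},
        "paths": {},
    }

    def seed_for(stage: str) -> int:
        s = derive_seed(cfg.seed, stage)
        manifest["stage_seeds"][stage] = s
        return s

    # -- simulate ----------------------------------------------------------
    @_stage("simulate")
    def simulate():
        world = synthetic.generate_world(
            dataclasses.replace(cfg.world, seed=seed_for("world")))
        records, gt = synthetic.generate_users(
            world, dataclasses.replace(cfg.cohort, seed=seed_for("users")))
        gio.write_world_json(world, outdir / "world.json")
        gio.write_logs_tsv(records, outdir / "logs.tsv")
        gt.to_csv(outdir / "ground_truth.csv", index=False)
        return world, records, gt

    world, records, gt = simulate()
    manifest["paths"].update(world="world.json", logs="logs.tsv",
                             ground_truth="ground_truth.csv")

    # -- cohort ------------------------------------------------------------
    @_stage("cohort")
    def cohort():
        visits = geofence.detect_facility_visits(records, world.facilities,
                                                 cfg.geofence)
        patients = geofence.apply_cohort_filters(records, visits,
                                                 world.facilities, cfg.geofence)
        controls = geofence.sample_controls(records, patients, visits,
                                            cfg.geofence, seed_for("controls"))
        windows = geofence.build_windows(records, patients, controls,
                                         cfg.geofence, seed_for("windows"),
                                         cfg.features.n_window_days)
        table = pd.DataFrame(
            [(w.user_id, w.label, w.endpoint_time, len(w.records)) for w in windows],
            columns=["user_id", "label", "endpoint_time", "n_records"])
        table.to_csv(outdir / "cohort.csv", index=False)
        return visits, patients, controls, windows

    visits, patients, controls, windows = cohort()
    manifest["paths"]["cohort"] = "cohort.csv"
    manifest["metrics"]["n_patients"] = int(len(patients))
    manifest["metrics"]["n_controls"] = int(len(controls))

    # -- features ----------------------------------------------------------
    @_stage("features")
    def features():
        users = sorted(w.user_id for w in windows)
        y = pd.Series({w.user_id: 1 if w.label == "patient" else 0
                       for w in windows}).reindex(users)
        dummy = pd.DataFrame(index=pd.Index(users, name="user_id"))
        tr, te = models.split_train_test(dummy, y, cfg.train_fraction,
                                         seed_for("split"))
        resolver = LandmarkResolver(world.landmarks, cfg.features,
                                    cfg.geofence.earth_radius_m)
        train_windows = [w for w in windows if w.user_id in set(tr)]
        selections = fit_selections(train_windows, resolver, cfg.features)
        matrices = build_matrices(windows, world.lexicon, resolver,
                                  selections, cfg.features)
        gio.write_matrices(matrices, outdir / "features")
        return tr, te, selections, matrices

    train_users, test_users, selections, matrices = features()
    manifest["paths"]["features"] = "features"
    manifest["metrics"]["n_enriched_tokens"] = len(selections.tokens)
    manifest["metrics"]["n_enriched_categories"] = len(selections.categories)
    manifest["metrics"]["n_location_name_tokens"] = len(selections.name_tokens)

    # -- train -------------------------------------------------------------
    @_stage("train")
    def train():
        spec = dataclasses.replace(cfg.model, seed=seed_for("model"))
        results = {}
        Xd, yd = matrices.xy("daywise")
        res_d = models.fit_and_score(Xd.loc[train_users], yd.loc[train_users],
                                     Xd.loc[test_users], yd.loc[test_users], spec)
        results["daywise"] = res_d
        Xa, ya = matrices.xy("aggregate")
        res_a = models.fit_and_score(Xa.loc[train_users], ya.loc[train_users],
                                     Xa.loc[test_users], ya.loc[test_users], spec)
        results["aggregate"] = res_a
        ablation = None
        if cfg.ablate:
            ablation = models.ablation_study(Xd, yd, matrices.daywise_categories,
                                             spec, cfg.train_fraction,
                                             seed_for("ablation"))
        roc = pd.DataFrame({"fpr": res_d.fpr, "tpr": res_d.tpr})
        roc.to_csv(outdir / "roc_daywise.csv", index=False)
        return results, ablation

    results, ablation = train()
    manifest["paths"]["roc_daywise"] = "roc_daywise.csv"
    manifest["metrics"]["daywise"] = results["daywise"].summary()
    manifest["metrics"]["aggregate"] = results["aggregate"].summary()
    if ablation is not None:
        manifest["metrics"]["ablation"] = ablation

    # -- evaluate ----------------------------------------------------------
    @_stage("evaluate")
    def evaluate():
        ads_cfg = dataclasses.replace(cfg.ads, seed=seed_for("ads"))
        scores = results["daywise"].scores
        test_gt = gt[gt["user_id"].isin(scores.index)]
        impressions, ad_visits = synthetic.generate_ad_stream(
            test_gt, world.facilities, ads_cfg)
        converted = adeval.label_conversions(impressions, ad_visits,
                                             cfg.conversion)
        scored = pd.DataFrame({
            "user_id": converted.index,
            "score": scores.reindex(converted.index).fillna(0.0).to_numpy(),
            "converted": converted.to_numpy(),
        })
        T = min(cfg.conversion.window_T, len(scored))
        curve = adeval.local_show_conversion_rate(scored, T)
        curve[["percentile", "local_rate"]].to_csv(
            outdir / "conversion_curve.csv", index=False)
        if curve["local_rate"].nunique() > 1:
            rho = float(sps.spearmanr(curve["percentile"],
                                      curve["local_rate"]).statistic)
        else:
            rho = 0.0

        # A/B demo: split scored users, target B's impressions by coefficient
        rng = np.random.default_rng(seed_for("ab_split"))
        users = scored["user_id"].to_numpy()
        mask_b = rng.random(len(users)) < 0.5
        coef = {u: adeval.score_to_coefficient(s)
                for u, s in zip(scored["user_id"], scored["score"])}
        gt_a = test_gt[test_gt["user_id"].isin(users[~mask_b])]
        gt_b = test_gt[test_gt["user_id"].isin(users[mask_b])]
        imp_a, vis_a = synthetic.generate_ad_stream(
            gt_a, world.facilities,
            dataclasses.replace(ads_cfg, seed=seed_for("ads_a")))
        imp_b, vis_b = synthetic.generate_ad_stream(
            gt_b, world.facilities,
            dataclasses.replace(ads_cfg, seed=seed_for("ads_b")),
            show_weight=coef)
        ab = None
        if len(imp_a) and len(imp_b):
            conv_a = adeval.label_conversions(imp_a, vis_a, cfg.conversion)
            conv_b = adeval.label_conversions(imp_b, vis_b, cfg.conversion)
            ga = imp_a.assign(converted=conv_a.reindex(imp_a["user_id"]).to_numpy())
            gb = imp_b.assign(converted=conv_b.reindex(imp_b["user_id"]).to_numpy())
            # only the first impression of a converting user counts as converted
            ga["converted"] = ga["converted"] & ~ga.duplicated(["user_id"])
            gb["converted"] = gb["converted"] & ~gb.duplicated(["user_id"])
            ab = adeval.ab_metrics(ga, gb)
        return {"conversion_curve_spearman": rho,
                "global_conversion_rate": float(scored["converted"].mean()),
                "ab": ab}

    manifest["metrics"]["evaluation"] = _json_safe(evaluate())
    manifest["paths"]["conversion_curve"] = "conversion_curve.csv"
    manifest["paths"]["manifest"] = "manifest.json"
    manifest["config"] = to_dict(cfg)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
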