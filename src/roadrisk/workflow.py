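"""End-to-end orchestration: simulate -> encode -> schedule -> three
generations -> risk index -> impact model -> evaluation.

Every stage seed derives from the config's master seed, so a config hash
plus master seed pins the entire run; rerunning with the same config
yields byte-identical JSON reports.  Artifacts are stamped with the
config hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .evaluation import prevalence_auc
from .impact import (
    aggregate_impact,
    attach_impact,
    prepare_impact_predictors,
    train_impact_model,
)
from .pipeline import (
    add_focal_variants,
    encode_landscape,
    filter_variables,
    prepare_training,
    run_generation1,
    run_generation2,
    run_generation3,
    training_union,
)
from .risk import HoldSpec, build_risk_surface
from .seeds import derive_seed
from .synthetic import generate_impact_fine, generate_landscape

__all__ = ["run_pipeline", "candidate_variables"]


def candidate_variables(landscape, focal_groups: dict, encoded_cols: list) -> list:
    """Generation-1 candidate list: continuous covariates, focal-mean
    variants, and rank-encoded categoricals (raw class labels excluded)."""
    continuous = [
        c for c, f in landscape.forms.items() if f != "categorical-blocks"
    ]
    focal_cols = [
        v for variants in focal_groups.values() for v in variants[1:]
    ]
    return continuous + focal_cols + list(encoded_cols)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full routine under one master seed.

    Returns a dict of in-memory artifacts; when ``out_dir`` is given the
    JSON/CSV reports (plan, generation summaries, risk summary,
    evaluation reports) are also written there, each stamped with the
    config hash.
    """
    config.validate()
    master = config.master_seed
    tr = config.training
    nbh = config.neighborhood()

    # -- simulate -------------------------------------------------------
    landscape = generate_landscape(config.build_regions())
    fine = generate_impact_fine(
        landscape.table,
        gamma_road=config.impact.gamma_road,
        gamma_base=config.impact.gamma_base,
        seed=derive_seed(master, "impact-fine"),
    )
    impact_response = aggregate_impact(fine, threshold=config.impact.threshold)
    landscape.table = attach_impact(landscape.table, impact_response)

    # -- schedule + encode ---------------------------------------------
    plan, ssets = prepare_training(
        landscape.table, tr.counts, tr.multiplicities,
        tr.subsample_presence, tr.subsample_absence, tr.trees_per_iteration,
        seed=derive_seed(master, "sampling"), mode=tr.mode,
    )
    train_idx = training_union(ssets)
    table, encodings, encoded_cols = encode_landscape(
        landscape, fit_indices=train_idx
    )
    table, focal_groups = add_focal_variants(
        table, landscape.grid_shapes, config.focal_variants
    )
    variant_groups = dict(focal_groups)
    variant_groups["protected_area"] = [
        "protected_area__rank", "protected_area__rank_by_country"
    ]
    variables = candidate_variables(landscape, focal_groups, encoded_cols)

    # -- three generations ---------------------------------------------
    rec1 = run_generation1(
        table, variables, plan, ssets,
        tr.per_tree_presence, tr.per_tree_absence,
        seed=derive_seed(master, "generations"), tree_params=tr.tree_params,
        n_eval_per_region=config.n_eval_per_region_importance,
        n_importance_reps=config.n_importance_reps,
    )
    kept = filter_variables(rec1.importance, variant_groups)
    rec2, table_sar = run_generation2(
        table, kept, plan, ssets, tr.per_tree_presence, tr.per_tree_absence,
        seed=derive_seed(master, "generations"), grid_shapes=landscape.grid_shapes,
        neighborhood=nbh, tree_params=tr.tree_params,
    )
    rec3 = run_generation3(
        table_sar, kept, plan, ssets, tr.per_tree_presence, tr.per_tree_absence,
        seed=derive_seed(master, "generations"), grid_shapes=landscape.grid_shapes,
        neighborhood=nbh, tree_params=tr.tree_params,
    )

    # -- risk index -----------------------------------------------------
    hold = HoldSpec.from_kinds(rec3.model.variables, landscape.kinds).freeze_means(
        table_sar.loc[train_idx]
    )
    risk = build_risk_surface(rec3.model, table_sar, hold)

    # -- impact model ----------------------------------------------------
    impact_table = prepare_impact_predictors(
        table_sar, risk.values, fit_indices=train_idx
    )
    impact_model, impact_pd, impact_art = train_impact_model(
        impact_table, tr.counts, tr.multiplicities,
        tr.subsample_presence, tr.subsample_absence, tr.trees_per_iteration,
        tr.per_tree_presence, tr.per_tree_absence,
        seed=derive_seed(master, "impact-model"), tree_params=tr.tree_params,
        mode="resample",
    )

    # -- evaluation ------------------------------------------------------
    road_report = prevalence_auc(
        rec3.model, table_sar, config.evaluation.n_iterations,
        config.evaluation.n_per_region, seed=derive_seed(master, "road-eval"),
        scope="pantropical", morans=rec3.morans,
    )
    impact_report = prevalence_auc(
        impact_model, impact_table, config.evaluation.n_iterations,
        config.evaluation.n_per_region, seed=derive_seed(master, "impact-eval"),
        response="impact_present", scope="impact", sar_zero=False,
    )

    results = {
        "config": config,
        "landscape": landscape,
        "table": table_sar,
        "impact_table": impact_table,
        "plan": plan,
        "subsample_sets": ssets,
        "encodings": encodings,
        "variant_groups": variant_groups,
        "records": {1: rec1, 2: rec2, 3: rec3},
        "kept_variables": kept,
        "risk": risk,
        "impact_model": impact_model,
        "impact_partial_dependence": impact_pd,
        "road_report": road_report,
        "impact_report": impact_report,
    }
    if out_dir is not None:
        _write_artifacts(results, Path(out_dir))
    return results


def _write_artifacts(results: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = results["config"]
    stamp = {"config_hash": config.config_hash(), "master_seed": config.master_seed}

    config.to_yaml(out_dir / "config.yaml")
    results["plan"].to_json(out_dir / "plan.json")

    risk = results["risk"]
    report = {
        **stamp,
        "generations": {
            g: rec.summary() for g, rec in sorted(results["records"].items())
        },
        "kept_variables": list(results["kept_variables"]),
        "risk": {
            "threshold_raw": risk.threshold_raw,
            "min_raw": risk.min_raw,
            "max_raw": risk.max_raw,
            "mean_risk_road": float(
                risk.values[results["table"]["road_present"] == 1].mean()
            ),
            "mean_risk_no_road": float(
                risk.values[results["table"]["road_present"] == 0].mean()
            ),
        },
        "road_evaluation": results["road_report"].to_dict(),
        "impact_evaluation": results["impact_report"].to_dict(),
        "road_prevalence": {
            r: float(v)
            for r, v in sorted(results["landscape"].road_prevalence.items())
        },
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)

    results["records"][1].importance.to_csv(
        out_dir / "gen1_importance.csv", index=False
    )
    results["impact_partial_dependence"].to_csv(
        out_dir / "impact_partial_dependence.csv", index=False
    )


def _round_floats(obj, digits: int = 10):
    """Round floats for stable, byte-identical JSON across reruns."""
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
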