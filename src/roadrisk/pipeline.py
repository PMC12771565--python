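"""The three-generation modelling routine.

Generation 1 fits the forest on every candidate covariate and measures
permutation importance on a held-out, original-prevalence sample.
Variables with MDA <= 0 are dropped, and within each variant group
(the same quantity measured at several focal scales or with several
encodings) only the most important variant survives.  Generation 2
refits on the reduced set, predicts the whole landscape, and turns the
residuals into a residuals autocovariate (SAR term) — the neighbourhood
mean of generation-2 residuals.  Generation 3 refits with the SAR term
appended; all performance and prediction paths afterwards hold the SAR
term at 0 so it absorbs autocorrelation without leaking into forecasts.
Moran's I of the residual grids is the diagnostic at each step.

The same second/third-generation routine can be restricted to a single
region to produce region-specific models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import apply_rank_encoding, fit_rank_encoding
from .forest import ForestModel, permutation_importance, predict_proba, train_forest
from .sampling import (
    IterationPlan,
    build_iteration_plan,
    build_subsamples,
    draw_prevalence_sample,
)
from .seeds import derive_seed
from .spatial import NeighborhoodSpec, focal_mean, morans_i, residual_autocovariate
from .synthetic import Landscape

__all__ = [
    "GenerationRecord",
    "encode_landscape",
    "add_focal_variants",
    "prepare_training",
    "training_union",
    "run_generation1",
    "filter_variables",
    "run_generation2",
    "run_generation3",
    "run_region_specific",
    "hold_sar_zero",
    "SAR_TERM",
]

SAR_TERM = "sar_term"


@dataclass
class GenerationRecord:
    """Outcome of one model generation."""

    generation: int
    variables: list
    model: ForestModel
    importance: pd.DataFrame | None = None
    morans: dict = field(default_factory=dict)  # region -> residual Moran's I

    def summary(self) -> dict:
        out = {
            "generation": self.generation,
            "variables": list(self.variables),
            "n_trees": self.model.n_trees,
            "morans_i": {r: float(v) for r, v in sorted(self.morans.items())},
        }
        if self.importance is not None:
            out["importance"] = {
                row["variable"]: round(float(row["mda"]), 10)
                for _, row in self.importance.iterrows()
            }
        return out


def training_union(subsample_sets: dict) -> np.ndarray:
    """Union of all subsample indices — the model training sample."""
    parts = [np.concatenate(s.subsamples) for s in subsample_sets.values()]
    return np.unique(np.concatenate(parts))


def encode_landscape(
    landscape: Landscape,
    response: str = "road_present",
    fit_indices: np.ndarray | None = None,
    suffix: str = "__rank",
    country_variants: tuple = ("protected_area",),
) -> tuple[pd.DataFrame, dict, list]:
    """Rank-encode the landscape's categorical covariates.

    Encodings are fitted on ``fit_indices`` (the model training sample)
    when given, otherwise on the full table, and applied to every cell
    with the median-rank policy for classes absent from the fit.  For the
    covariates in ``country_variants`` a second, per-country (here:
    per-region) encoding is added so the two flavours can compete as a
    variant group.

    Returns (encoded table, fitted encodings, encoded column names).
    """
    table = landscape.table.copy()
    fit_rows = table.loc[fit_indices] if fit_indices is not None else table
    encodings: dict = {}
    encoded_cols: list = []
    categorical = [c for c, f in landscape.forms.items() if f == "categorical-blocks"]
    for name in categorical:
        enc = fit_rank_encoding(
            fit_rows[name], fit_rows[response], variable=name
        )
        col = name + suffix
        table[col] = apply_rank_encoding(enc, table[name], unseen="median")
        encodings[name] = enc
        encoded_cols.append(col)
        if name in country_variants:
            enc_c = fit_rank_encoding(
                fit_rows[name],
                fit_rows[response],
                groups=fit_rows["region"],
                variable=name + "_by_country",
            )
            col_c = name + suffix + "_by_country"
            table[col_c] = apply_rank_encoding(
                enc_c, table[name], groups=table["region"], unseen="median"
            )
            encodings[name + "_by_country"] = enc_c
            encoded_cols.append(col_c)
    return table, encodings, encoded_cols


def add_focal_variants(
    table: pd.DataFrame,
    grid_shapes: dict,
    focal: dict,
) -> tuple[pd.DataFrame, dict]:
    """Add focal-mean variants of covariates at several window radii.

    ``focal`` maps covariate name -> list of radii (cells); each radius r
    adds a column ``{name}_f{r}`` holding the circular focal mean on the
    region grid.  Returns the augmented table and the variant-group
    mapping {name: [name, name_f{r1}, ...]}.
    """
    table = table.copy()
    groups: dict = {}
    for name, radii in focal.items():
        variants = [name]
        for r in radii:
            col = f"{name}_f{r}"
            values = np.empty(len(table))
            for region, shape in grid_shapes.items():
                mask = (table["region"] == region).to_numpy()
                sub = table[mask]
                grid = np.empty(shape)
                grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub[
                    name
                ].to_numpy(float)
                smoothed = focal_mean(grid, r)
                values[mask] = smoothed[sub["row"].to_numpy(), sub["col"].to_numpy()]
            table[col] = values
            variants.append(col)
        groups[name] = variants
    return table, groups


def prepare_training(
    table: pd.DataFrame,
    counts: dict,
    multiplicities: dict,
    n_presence: int,
    n_absence: int,
    trees_per_iteration: int,
    seed: int,
    mode: str = "partition",
    response: str = "road_present",
) -> tuple[IterationPlan, dict]:
    """Build per-region subsamples and the iteration plan."""
    subsample_sets = {
        region: build_subsamples(
            table,
            region,
            n_presence,
            n_absence,
            counts[region],
            seed=derive_seed(seed, "subsample", region),
            mode=mode,
            response=response,
        )
        for region in sorted(counts)
    }
    plan = build_iteration_plan(
        counts, multiplicities, trees_per_iteration, seed=derive_seed(seed, "plan")
    )
    return plan, subsample_sets


def run_generation1(
    table: pd.DataFrame,
    variables: list,
    plan: IterationPlan,
    subsample_sets: dict,
    n_presence: int,
    n_absence: int,
    seed: int,
    tree_params: dict | None = None,
    response: str = "road_present",
    n_eval_per_region: int = 2000,
    n_importance_reps: int = 3,
) -> GenerationRecord:
    """First generation: fit on all candidate variables, measure MDA.

    Importance is evaluated on a held-out draw at original prevalence,
    disjoint from the training subsamples.
    """
    model = train_forest(
        plan, table, variables, subsample_sets, n_presence, n_absence,
        seed=derive_seed(seed, "gen1"), tree_params=tree_params,
        response=response, generation=1,
    )
    held_out = draw_prevalence_sample(
        table,
        n_eval_per_region,
        seed=derive_seed(seed, "gen1-eval"),
        response=response,
        exclude=training_union(subsample_sets),
    )
    importance = permutation_importance(
        model,
        table.loc[held_out],
        n_reps=n_importance_reps,
        seed=derive_seed(seed, "gen1-mda"),
        response=response,
    )
    return GenerationRecord(1, list(variables), model, importance=importance)


def filter_variables(importance, groups: dict | None = None) -> list:
    """Reduce the variable list from generation-1 importance.

    Drops every variable with MDA <= 0 (negative permutation importance
    is noise), then keeps exactly the arg-max variant inside each variant
    group, breaking ties toward the lexicographically first name.
    Ungrouped survivors are kept; the output preserves the importance
    table's order.
    """
    if isinstance(importance, pd.DataFrame):
        mda = dict(zip(importance["variable"], importance["mda"]))
        order = list(importance["variable"])
    else:
        mda = dict(importance)
        order = list(mda)
    groups = groups or {}
    for base, variants in groups.items():
        unknown = [v for v in variants if v not in mda]
        if unknown:
            raise ValueError(
                f"variant group {base!r} references variables absent from the "
                f"importance table: {unknown}"
            )
    survivors = {v for v, m in mda.items() if m > 0}
    grouped = set()
    keep_from_groups = set()
    for base, variants in groups.items():
        grouped.update(variants)
        alive = [v for v in variants if v in survivors]
        if alive:
            best = min(alive, key=lambda v: (-mda[v], v))
            keep_from_groups.add(best)
    return [
        v
        for v in order
        if (v in survivors and v not in grouped) or v in keep_from_groups
    ]


def _landscape_residual_grids(
    table: pd.DataFrame,
    proba: np.ndarray,
    grid_shapes: dict,
    response: str,
) -> dict:
    residual = table[response].to_numpy(float) - proba
    grids = {}
    rows = table["row"].to_numpy()
    cols = table["col"].to_numpy()
    regions = table["region"].to_numpy()
    for region, shape in grid_shapes.items():
        mask = regions == region
        grid = np.zeros(shape)
        grid[rows[mask], cols[mask]] = residual[mask]
        grids[region] = grid
    return grids


def run_generation2(
    table: pd.DataFrame,
    kept_variables: list,
    plan: IterationPlan,
    subsample_sets: dict,
    n_presence: int,
    n_absence: int,
    seed: int,
    grid_shapes: dict,
    neighborhood: NeighborhoodSpec = NeighborhoodSpec(),
    tree_params: dict | None = None,
    response: str = "road_present",
    chunk_size: int = 200_000,
) -> tuple[GenerationRecord, pd.DataFrame]:
    """Second generation: refit on the kept variables and build the SAR term.

    The model predicts the whole landscape (chunked; output independent
    of chunking), residuals are observed - predicted probability, and the
    SAR term is the neighbourhood mean of the residual grid.  Returns the
    record (with per-region residual Moran's I) and the table augmented
    with ``gen2_proba``, ``gen2_residual`` and the SAR column.
    """
    model = train_forest(
        plan, table, kept_variables, subsample_sets, n_presence, n_absence,
        seed=derive_seed(seed, "gen2"), tree_params=tree_params,
        response=response, generation=2,
    )
    proba = predict_proba(model, table, chunk_size=chunk_size)
    grids = _landscape_residual_grids(table, proba, grid_shapes, response)
    morans = {r: morans_i(g, neighborhood) for r, g in grids.items()}

    out = table.copy()
    out["gen2_proba"] = proba
    out["gen2_residual"] = out[response].to_numpy(float) - proba
    sar = np.empty(len(out))
    rows = out["row"].to_numpy()
    cols = out["col"].to_numpy()
    regions = out["region"].to_numpy()
    for region, grid in grids.items():
        mask = regions == region
        sar_grid = residual_autocovariate(grid, neighborhood)
        sar[mask] = sar_grid[rows[mask], cols[mask]]
    out[SAR_TERM] = sar
    record = GenerationRecord(2, list(kept_variables), model, morans=morans)
    return record, out


def hold_sar_zero(table: pd.DataFrame) -> pd.DataFrame:
    """Copy of the table with the SAR term held at 0 (prediction contract)."""
    out = table.copy()
    if SAR_TERM in out.columns:
        out[SAR_TERM] = 0.0
    return out


def run_generation3(
    table: pd.DataFrame,
    kept_variables: list,
    plan: IterationPlan,
    subsample_sets: dict,
    n_presence: int,
    n_absence: int,
    seed: int,
    grid_shapes: dict,
    neighborhood: NeighborhoodSpec = NeighborhoodSpec(),
    tree_params: dict | None = None,
    response: str = "road_present",
    chunk_size: int = 200_000,
) -> GenerationRecord:
    """Third generation: refit with the SAR term appended.

    The final model's variable list is the generation-2 list plus the SAR
    term.  The diagnostic Moran's I here is computed on residuals with
    the SAR term *active* (its stored values), which is what the term is
    meant to flatten; every performance or forecasting path instead runs
    through :func:`hold_sar_zero`.
    """
    if SAR_TERM not in table.columns:
        raise ValueError("SAR term missing; run generation 2 first")
    variables = list(kept_variables) + [SAR_TERM]
    model = train_forest(
        plan, table, variables, subsample_sets, n_presence, n_absence,
        seed=derive_seed(seed, "gen3"), tree_params=tree_params,
        response=response, generation=3,
    )
    proba = predict_proba(model, table, chunk_size=chunk_size)
    grids = _landscape_residual_grids(table, proba, grid_shapes, response)
    morans = {r: morans_i(g, neighborhood) for r, g in grids.items()}
    return GenerationRecord(3, variables, model, morans=morans)


def run_region_specific(
    table: pd.DataFrame,
    region: str,
    kept_variables: list,
    n_subsamples: int,
    n_presence: int,
    n_absence: int,
    trees_per_iteration: int,
    seed: int,
    grid_shapes: dict,
    neighborhood: NeighborhoodSpec = NeighborhoodSpec(),
    tree_params: dict | None = None,
    response: str = "road_present",
    mode: str = "partition",
) -> dict:
    """Second and third generations restricted to one region.

    The plan degenerates to multiplicity 1 over the region's subsamples;
    the SAR term is rebuilt from the region-specific generation-2
    residuals.  Returns {"gen2": record, "gen3": record, "table": ...}.
    """
    if region not in set(table["region"]):
        raise ValueError(f"region {region!r} absent from table")
    sub = table[table["region"] == region].copy()
    counts = {region: n_subsamples}
    multiplicities = {region: 1}
    plan, ssets = prepare_training(
        sub, counts, multiplicities, n_presence, n_absence,
        trees_per_iteration, seed=derive_seed(seed, "region", region),
        mode=mode, response=response,
    )
    shapes = {region: grid_shapes[region]}
    rec2, sub_sar = run_generation2(
        sub, kept_variables, plan, ssets, n_presence, n_absence,
        seed=derive_seed(seed, "region-gen2", region), grid_shapes=shapes,
        neighborhood=neighborhood, tree_params=tree_params, response=response,
    )
    rec3 = run_generation3(
        sub_sar, kept_variables, plan, ssets, n_presence, n_absence,
        seed=derive_seed(seed, "region-gen3", region), grid_shapes=shapes,
        neighborhood=neighborhood, tree_params=tree_params, response=response,
    )
    return {"gen2": rec2, "gen3": rec3, "table": sub_sar, "plan": plan, "subsample_sets": ssets}
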