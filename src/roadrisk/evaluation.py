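"""Model evaluation and sensitivity harness.

Evaluation follows the prevalence-ratio protocol: repeated held-out
draws at each region's *original* prevalence (the training sample is
class-balanced by design, so evaluating on it would overestimate
predicted probabilities and inflate false positives), AUC per draw, and
mean/sd across draws, always with the SAR term held at 0.

The sensitivity harness retrains the shared routine under three
frameworks — class-balanced draws, original-prevalence draws, and
original-prevalence draws with class weights — on identical evaluation
draws, and compares performance and variable importance.  A tree-path
attribution (exactly additive per record) provides the alternative,
attribution-based variable-selection route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import ForestModel, permutation_importance, predict_proba, train_forest
from .pipeline import filter_variables, hold_sar_zero, prepare_training
from .sampling import draw_prevalence_sample
from .seeds import derive_seed
from .spatial import auc

__all__ = [
    "EvalReport",
    "prevalence_auc",
    "representativeness_report",
    "FrameworkComparison",
    "compare_frameworks",
    "tree_path_attribution",
    "shap_selection_variant",
]

FRAMEWORKS = ("balanced", "original-prevalence", "class-weighted")


@dataclass
class EvalReport:
    """Prevalence-ratio AUC summary for one model scope."""

    scope: str
    auc_mean: float
    auc_sd: float
    n_iterations: int
    n_per_region: int
    per_region: dict = field(default_factory=dict)  # region -> (mean, sd)
    morans_mean: float | None = None
    morans_sd: float | None = None
    seeds: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "n_iterations": self.n_iterations,
            "n_per_region": self.n_per_region,
            "per_region": {
                r: {"auc_mean": m, "auc_sd": s}
                for r, (m, s) in sorted(self.per_region.items())
            },
            "morans_mean": self.morans_mean,
            "morans_sd": self.morans_sd,
            "seeds": list(self.seeds),
        }


def prevalence_auc(
    model: ForestModel,
    table: pd.DataFrame,
    n_iterations: int,
    n_per_region: int,
    seed: int,
    response: str | None = None,
    scope: str = "pantropical",
    regions: list | None = None,
    sar_zero: bool = True,
    morans: dict | None = None,
    pooling: str = "pooled",
) -> EvalReport:
    """Repeated prevalence-ratio evaluation.

    Each iteration draws ``n_per_region`` records per region at the
    region's original prevalence, scores them with the SAR term held at
    0, and computes AUC — pooled across regions by default
    (``pooling="pooled"``) as well as per region.  The report records the
    per-iteration seeds for exact re-runs, and optionally embeds residual
    Moran's I diagnostics computed upstream.
    """
    if pooling not in ("pooled", "mean-of-regions"):
        raise ValueError(f"unknown pooling {pooling!r}")
    response = response or model.response
    if regions is None:
        regions = sorted(table["region"].unique())
    eval_table = hold_sar_zero(table) if sar_zero else table
    iter_seeds = [derive_seed(seed, "auc-iter", i) for i in range(n_iterations)]
    pooled = np.empty(n_iterations)
    per_region_vals: dict = {r: np.empty(n_iterations) for r in regions}
    for i, s in enumerate(iter_seeds):
        idx = draw_prevalence_sample(
            eval_table, n_per_region, seed=s, response=response, regions=regions
        )
        rows = eval_table.loc[idx]
        scores = predict_proba(model, rows)
        labels = rows[response].to_numpy()
        region_col = rows["region"].to_numpy()
        region_aucs = []
        for r in regions:
            mask = region_col == r
            value = auc(labels[mask], scores[mask])
            per_region_vals[r][i] = value
            region_aucs.append(value)
        pooled[i] = (
            auc(labels, scores) if pooling == "pooled" else float(np.mean(region_aucs))
        )
    morans_mean = morans_sd = None
    if morans:
        vals = np.array(list(morans.values()), dtype=float)
        morans_mean = float(vals.mean())
        morans_sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return EvalReport(
        scope=scope,
        auc_mean=float(pooled.mean()),
        auc_sd=float(pooled.std(ddof=1)) if n_iterations > 1 else 0.0,
        n_iterations=n_iterations,
        n_per_region=n_per_region,
        per_region={
            r: (
                float(v.mean()),
                float(v.std(ddof=1)) if n_iterations > 1 else 0.0,
            )
            for r, v in per_region_vals.items()
        },
        morans_mean=morans_mean,
        morans_sd=morans_sd,
        seeds=iter_seeds,
    )


def representativeness_report(
    training_sample: pd.DataFrame,
    full_table: pd.DataFrame,
    variables: list,
    n_quantiles: int = 20,
) -> pd.DataFrame:
    """Quantile-by-quantile comparison of training sample vs full landscape.

    For each shared variable, paired quantiles of the training sample and
    the full table are reported with their gap; the comparison is
    deliberately descriptive (no hypothesis test — at landscape sample
    sizes any test would flag trivially small differences).
    """
    qs = np.arange(1, n_quantiles) / n_quantiles
    records = []
    for var in variables:
        t = training_sample[var].astype(float).quantile(qs).to_numpy()
        f = full_table[var].astype(float).quantile(qs).to_numpy()
        for q, tv, fv in zip(qs, t, f):
            records.append(
                {
                    "variable": var,
                    "quantile": float(q),
                    "training": float(tv),
                    "full": float(fv),
                    "gap": float(tv - fv),
                }
            )
    out = pd.DataFrame(records)
    out["abs_gap"] = out["gap"].abs()
    return out


@dataclass
class FrameworkComparison:
    """Paired comparison of sampling frameworks on identical eval draws."""

    performance: pd.DataFrame  # framework, auc_mean, auc_sd
    importance: pd.DataFrame  # framework, variable, mda, se
    models: dict = field(default_factory=dict)


def compare_frameworks(
    table: pd.DataFrame,
    frameworks: list,
    counts: dict,
    multiplicities: dict,
    n_presence: int,
    n_absence: int,
    trees_per_iteration: int,
    per_tree_presence: int,
    per_tree_absence: int,
    seed: int,
    tree_params: dict | None = None,
    response: str = "road_present",
    mode: str = "partition",
    n_eval_iterations: int = 10,
    n_eval_per_region: int = 2000,
    n_importance_reps: int = 3,
) -> FrameworkComparison:
    """Train the shared routine under each sampling framework and compare.

    Frameworks differ only in per-tree class counts/weights: ``balanced``
    uses equal counts; ``original-prevalence`` draws at the pool's own
    prevalence; ``class-weighted`` adds inverse-frequency class weights
    on top of original-prevalence draws.  Subsamples, the iteration plan,
    and every held-out evaluation draw are bit-identical across
    frameworks (paired comparison).
    """
    unknown = [f for f in frameworks if f not in FRAMEWORKS]
    if unknown:
        raise ValueError(f"unknown frameworks: {unknown}")
    plan, ssets = prepare_training(
        table, counts, multiplicities, n_presence, n_absence,
        trees_per_iteration, seed=derive_seed(seed, "fw-sampling"),
        mode=mode, response=response,
    )
    eval_seed = derive_seed(seed, "fw-eval")
    mda_seed = derive_seed(seed, "fw-mda")
    mda_idx = draw_prevalence_sample(
        table, n_eval_per_region, seed=mda_seed, response=response
    )
    perf_rows = []
    imp_frames = []
    models = {}
    for fw in frameworks:
        count_policy = "balanced" if fw == "balanced" else "prevalence"
        class_weight = "balanced" if fw == "class-weighted" else None
        model = train_forest(
            plan, table, _model_variables(table, response), ssets,
            per_tree_presence, per_tree_absence,
            seed=derive_seed(seed, "fw-train", fw),
            tree_params=tree_params, response=response,
            count_policy=count_policy, class_weight=class_weight,
        )
        models[fw] = model
        report = prevalence_auc(
            model, table, n_eval_iterations, n_eval_per_region,
            seed=eval_seed, response=response, scope=fw, sar_zero=False,
        )
        perf_rows.append(
            {"framework": fw, "auc_mean": report.auc_mean, "auc_sd": report.auc_sd}
        )
        imp = permutation_importance(
            model, table.loc[mda_idx], n_reps=n_importance_reps,
            seed=mda_seed, response=response,
        )
        imp.insert(0, "framework", fw)
        imp_frames.append(imp)
    return FrameworkComparison(
        performance=pd.DataFrame(perf_rows),
        importance=pd.concat(imp_frames, ignore_index=True),
        models=models,
    )


def _model_variables(table: pd.DataFrame, response: str) -> list:
    """All numeric non-structural columns — the framework-comparison set."""
    skip = {
        "cell_id", "row", "col", response,
        "road_present", "impact_present", "impacted_fraction",
        "gen2_proba", "gen2_residual",
    }
    return [
        c
        for c in table.columns
        if c not in skip and pd.api.types.is_numeric_dtype(table[c])
    ]


def tree_path_attribution(
    model: ForestModel, table: pd.DataFrame
) -> tuple[np.ndarray, float, np.ndarray]:
    """Exact per-record tree-path attributions.

    Walking each record's decision path, the change in the node's
    presence fraction across every split is credited to the split
    variable.  Attributions are exactly additive: for every record,
    base + sum(attributions) equals the model's mean per-tree leaf
    presence probability.

    Returns (attributions of shape (n_records, n_variables), base value,
    per-record leaf-probability predictions).
    """
    X = table[model.variables].to_numpy(dtype=float)
    n, p = X.shape
    contrib = np.zeros((n, p))
    preds = np.zeros(n)
    base = 0.0
    for tree in model.trees:
        t = tree.tree_
        pos = int(np.flatnonzero(tree.classes_ == 1)[0])
        value = t.value[:, 0, :]
        frac = value[:, pos] / value.sum(axis=1)
        base += frac[0]
        left, right = t.children_left, t.children_right
        feature, threshold = t.feature, t.threshold
        for i in range(n):
            node = 0
            while left[node] != -1:
                f = feature[node]
                nxt = left[node] if X[i, f] <= threshold[node] else right[node]
                contrib[i, f] += frac[nxt] - frac[node]
                node = nxt
            preds[i] += frac[node]
    n_trees = model.n_trees
    return contrib / n_trees, base / n_trees, preds / n_trees


def shap_selection_variant(
    model: ForestModel,
    table: pd.DataFrame,
    groups: dict | None = None,
    sample: int = 2000,
    seed: int = 0,
) -> tuple[list, pd.DataFrame]:
    """Variable selection by mean absolute tree-path attribution.

    The alternative to MDA-based filtering: per-variable mean absolute
    attributions (computed on a seeded subsample at reduced scale) stand
    in for MDA in the same filtering rule (drop zero attribution, keep
    the arg-max variant per group).  Returns (kept variables, attribution
    table).
    """
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=min(sample, len(table)), replace=False)
    contrib, _, _ = tree_path_attribution(model, table.iloc[idx])
    mean_abs = np.abs(contrib).mean(axis=0)
    attributions = pd.DataFrame(
        {"variable": model.variables, "mda": mean_abs}
    )
    kept = filter_variables(attributions, groups)
    return kept, attributions.rename(columns={"mda": "mean_abs_attribution"})
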