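"""Human-impact response construction and the five-variable impact model.

The fine-scale (25 m) impact layer is aggregated to 1-ha cells as the
fraction of the 16 subcells showing impact, then binarised at a 10%
cut-off — low enough to catch genuine incursion, high enough to discard
cells where an isolated misclassified subcell would otherwise count as
impact.  The downstream model reuses the road model's region-balanced
sampling routine with exactly five predictors: the road expansion risk
index plus administrative region, population density, GDP and
protected-area class (these last ranked against the impact response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import apply_rank_encoding, fit_rank_encoding
from .forest import ForestModel, partial_dependence, train_forest
from .pipeline import prepare_training
from .seeds import derive_seed
from .synthetic import FineImpactGrid

__all__ = [
    "ImpactResponse",
    "aggregate_impact",
    "attach_impact",
    "prepare_impact_predictors",
    "train_impact_model",
    "IMPACT_THRESHOLD",
    "IMPACT_PREDICTORS",
]

IMPACT_THRESHOLD = 0.10
IMPACT_PREDICTORS = [
    "risk_index",
    "admin_region__rank_imp",
    "popdens",
    "gdp",
    "protected_area__rank_imp",
]


@dataclass
class ImpactResponse:
    """Aggregated 1-ha impact: fraction of subcells impacted, binarised."""

    cell_ids: np.ndarray
    impacted_fraction: np.ndarray
    impact_present: np.ndarray
    threshold: float


def aggregate_impact(
    fine: FineImpactGrid, threshold: float = IMPACT_THRESHOLD
) -> ImpactResponse:
    """Aggregate 16 subcell flags per cell and binarise at the cut-off.

    fraction = impacted subcells / 16; presence <=> fraction >= threshold
    (inclusive), so 2/16 = 0.125 is present and 1/16 = 0.0625 absent at
    the default 10% cut-off.
    """
    flags = np.asarray(fine.flags)
    if flags.ndim != 2 or flags.shape[1] != 16:
        raise ValueError("malformed fine grid: expected 16 subcells per cell")
    if not np.isin(flags, [0, 1]).all():
        raise ValueError("malformed fine grid: flags must be 0/1")
    fraction = flags.sum(axis=1) / 16.0
    present = (fraction >= threshold).astype(np.int8)
    return ImpactResponse(
        cell_ids=np.asarray(fine.cell_ids),
        impacted_fraction=fraction,
        impact_present=present,
        threshold=threshold,
    )


def attach_impact(table: pd.DataFrame, response: ImpactResponse) -> pd.DataFrame:
    """Join the aggregated impact columns onto the landscape table."""
    imp = pd.DataFrame(
        {
            "cell_id": response.cell_ids,
            "impacted_fraction": response.impacted_fraction,
            "impact_present": response.impact_present,
        }
    )
    out = table.merge(imp, on="cell_id", how="left", validate="one_to_one")
    if out["impact_present"].isna().any():
        raise ValueError("impact layer does not cover every cell")
    return out


def prepare_impact_predictors(
    table: pd.DataFrame,
    risk_values: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble the impact model's predictor columns.

    Adds ``risk_index`` and rank-encodes the administrative covariates
    against the impact response (classes are ranked by mean impact
    presence, not road presence).
    """
    out = table.copy()
    out["risk_index"] = np.asarray(risk_values, dtype=float)
    fit_rows = out.loc[fit_indices] if fit_indices is not None else out
    for name in ("admin_region", "protected_area"):
        enc = fit_rank_encoding(
            fit_rows[name], fit_rows["impact_present"], variable=name + "_imp"
        )
        out[name + "__rank_imp"] = apply_rank_encoding(enc, out[name], unseen="median")
    return out


def train_impact_model(
    table: pd.DataFrame,
    counts: dict,
    multiplicities: dict,
    n_presence: int,
    n_absence: int,
    trees_per_iteration: int,
    per_tree_presence: int,
    per_tree_absence: int,
    seed: int,
    tree_params: dict | None = None,
    mode: str = "resample",
    pd_grid: int = 11,
    pd_sample: int = 4000,
) -> tuple[ForestModel, pd.DataFrame, dict]:
    """Fit the five-variable impact model with the road model's routine.

    Subsampling, scheduling and per-tree balanced bootstrap draws are
    identical to the road model, with ``impact_present`` as the response.
    Returns (model, partial-dependence curve of the risk index, training
    artifacts).  Resample mode is the default because impact prevalence
    can be too low for a strict partition at desk scale.
    """
    missing = [v for v in IMPACT_PREDICTORS if v not in table.columns]
    if missing:
        raise ValueError(f"impact model predictors missing: {missing}")
    plan, ssets = prepare_training(
        table, counts, multiplicities, n_presence, n_absence,
        trees_per_iteration, seed=derive_seed(seed, "impact-sampling"),
        mode=mode, response="impact_present",
    )
    model = train_forest(
        plan, table, IMPACT_PREDICTORS, ssets, per_tree_presence, per_tree_absence,
        seed=derive_seed(seed, "impact-forest"), tree_params=tree_params,
        response="impact_present", generation=3,
    )
    rng = np.random.default_rng(derive_seed(seed, "impact-pd"))
    sample = table.iloc[
        rng.choice(len(table), size=min(pd_sample, len(table)), replace=False)
    ]
    curve = partial_dependence(model, sample, "risk_index", n_grid=pd_grid)
    return model, curve, {"plan": plan, "subsample_sets": ssets}
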