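"""The region-balanced, down-sampled forest.

Trees are ordinary CART classifiers, but the ensemble is assembled from
the iteration schedule rather than a single bootstrap: every iteration
pools one subsample per region, and each tree in the iteration is fitted
on its own balanced with-replacement draw from that pool.  Prediction is
classic vote aggregation — the presence probability of a record is the
fraction of trees voting presence — with the classification rule
presence <=> probability >= 0.5.

Variable importance is permutation MDA (mean decrease in accuracy) on a
held-out sample at original prevalence; the custom sampling breaks
classic out-of-bag bookkeeping, so a held-out sample stands in for it.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .sampling import IterationPlan, draw_tree_sample, iteration_pool
from .seeds import derive_seed

__all__ = [
    "ForestModel",
    "train_forest",
    "predict_proba",
    "predict_class",
    "permutation_importance",
    "partial_dependence",
]

DEFAULT_TREE_PARAMS = {
    "criterion": "gini",
    "max_features": "sqrt",
    "max_depth": None,
    "min_samples_leaf": 1,
}


@dataclass
class ForestModel:
    """Assembled forest: ordered trees plus training metadata."""

    trees: list
    variables: list
    generation: int = 1
    tree_params: dict = field(default_factory=dict)
    plan: IterationPlan | None = None
    response: str = "road_present"
    seed: int = 0
    version: str = "roadrisk-forest-1"

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ForestModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise ValueError(f"{path} does not contain a ForestModel")
        return model


def _design_matrix(table: pd.DataFrame, variables: list) -> np.ndarray:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing model variables: {missing}")
    X = table[variables].to_numpy(dtype=float)
    bad = [v for i, v in enumerate(variables) if not np.isfinite(X[:, i]).all()]
    if bad:
        raise ValueError(f"non-finite values in covariates: {bad}")
    return X


def train_forest(
    plan: IterationPlan,
    table: pd.DataFrame,
    variables: list,
    subsample_sets: dict,
    n_presence: int,
    n_absence: int,
    seed: int,
    tree_params: dict | None = None,
    response: str = "road_present",
    generation: int = 1,
    count_policy: str = "balanced",
    class_weight=None,
) -> ForestModel:
    """Fit the forest over the iteration plan.

    For every iteration, ``trees_per_iteration`` trees are fitted, each on
    an independent :func:`draw_tree_sample` from the iteration's pooled
    subsamples; the trees are concatenated into one model.  Per-tree
    seeds derive from (seed, iteration, tree), so training is
    order-independent.

    ``count_policy``:
      * ``"balanced"`` — every draw has exactly (n_presence, n_absence);
      * ``"prevalence"`` — draws of n_presence + n_absence records at the
        iteration pool's own prevalence (at least one per class), for
        original-prevalence sensitivity runs.

    ``class_weight`` is forwarded to the tree learner (e.g. ``"balanced"``
    for the class-weighted sensitivity framework).
    """
    params = dict(DEFAULT_TREE_PARAMS)
    if tree_params:
        params.update(tree_params)
    if count_policy not in ("balanced", "prevalence"):
        raise ValueError(f"unknown count policy {count_policy!r}")
    _design_matrix(table, variables)  # validate before the training loop

    trees = []
    for it in range(plan.n_iterations):
        if count_policy == "prevalence":
            pres, absn = iteration_pool(plan, it, subsample_sets, table, response)
            n_total = n_presence + n_absence
            prev = len(pres) / (len(pres) + len(absn))
            n_p = min(max(1, round(prev * n_total)), n_total - 1)
            n_a = n_total - n_p
        else:
            n_p, n_a = n_presence, n_absence
        for j in range(plan.trees_per_iteration):
            draw = draw_tree_sample(
                plan, it, table, subsample_sets, n_p, n_a,
                seed=derive_seed(seed, "draw", it, j), response=response,
            )
            rows = table.loc[draw.indices]
            X = rows[variables].to_numpy(dtype=float)
            y = rows[response].to_numpy()
            tree = DecisionTreeClassifier(
                random_state=derive_seed(seed, "tree", it, j),
                class_weight=class_weight,
                **params,
            )
            tree.fit(X, y)
            trees.append(tree)
    return ForestModel(
        trees=trees,
        variables=list(variables),
        generation=generation,
        tree_params=params,
        plan=plan,
        response=response,
        seed=seed,
    )


def predict_proba(
    model: ForestModel, table: pd.DataFrame, chunk_size: int | None = None
) -> np.ndarray:
    """Vote-fraction presence probability for every record.

    The probability is the fraction of trees voting presence, so the
    denominator is always the tree count and outputs lie on the grid
    k / n_trees.  ``chunk_size`` streams large tables; the output is
    identical regardless of chunking.
    """
    X = _design_matrix(table, model.variables)
    n = X.shape[0]
    out = np.zeros(n, dtype=float)
    step = n if chunk_size is None else max(1, int(chunk_size))
    for start in range(0, n, step):
        block = X[start : start + step]
        votes = np.zeros(block.shape[0], dtype=float)
        for tree in model.trees:
            votes += tree.predict(block)
        out[start : start + step] = votes / model.n_trees
    return out


def predict_class(model: ForestModel, table: pd.DataFrame) -> np.ndarray:
    """Presence classification under the rule probability >= 0.5."""
    return (predict_proba(model, table) >= 0.5).astype(np.int8)


def _accuracy(y: np.ndarray, proba: np.ndarray) -> float:
    return float(((proba >= 0.5).astype(int) == y).mean())


def permutation_importance(
    model: ForestModel,
    eval_table: pd.DataFrame,
    n_reps: int = 5,
    seed: int = 0,
    response: str | None = None,
) -> pd.DataFrame:
    """Permutation importance: mean decrease in accuracy (MDA).

    For every model variable, the evaluation column is shuffled
    ``n_reps`` times (seeded) and MDA(v) is the mean of
    accuracy(original) - accuracy(v permuted); ``se`` is the standard
    error over repetitions (0 for a single repetition).  A variable no
    tree splits on has MDA exactly 0.
    """
    response = response or model.response
    y = eval_table[response].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("importance evaluation requires both classes present")
    X = _design_matrix(eval_table, model.variables)
    base_proba = _tree_votes(model, X)
    base_acc = _accuracy(y, base_proba)

    records = []
    for vi, var in enumerate(model.variables):
        drops = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng(derive_seed(seed, "perm", var, rep))
            Xp = X.copy()
            Xp[:, vi] = rng.permutation(Xp[:, vi])
            drops[rep] = base_acc - _accuracy(y, _tree_votes(model, Xp))
        se = float(drops.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
        records.append({"variable": var, "mda": float(drops.mean()), "se": se})
    return pd.DataFrame(records)


def _tree_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    votes = np.zeros(X.shape[0], dtype=float)
    for tree in model.trees:
        votes += tree.predict(X)
    return votes / model.n_trees


def partial_dependence(
    model: ForestModel,
    table: pd.DataFrame,
    variable: str,
    n_grid: int = 11,
) -> pd.DataFrame:
    """Partial dependence of the vote fraction on one variable.

    For each grid value g spanning the variable's observed range,
    curve(g) is the mean predicted probability with every record's
    ``variable`` forced to g (all other values unchanged).  A constant
    variable yields a single-point curve with a warning.
    """
    if variable not in model.variables:
        raise ValueError(f"{variable!r} is not a model variable")
    X = _design_matrix(table, model.variables)
    vi = model.variables.index(variable)
    lo, hi = float(X[:, vi].min()), float(X[:, vi].max())
    if lo == hi:
        import warnings

        warnings.warn(f"variable {variable!r} is constant; single-point curve")
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, n_grid)
    means = np.empty(grid.size)
    for gi, g in enumerate(grid):
        Xg = X.copy()
        Xg[:, vi] = g
        means[gi] = _tree_votes(model, Xg).mean()
    return pd.DataFrame({"value": grid, "mean_probability": means})
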