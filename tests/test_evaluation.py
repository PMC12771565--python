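"""Prevalence-ratio evaluation, representativeness, sensitivity harness."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from conftest import make_stump_model
from roadrisk.evaluation import (
    compare_frameworks,
    prevalence_auc,
    representativeness_report,
    shap_selection_variant,
    tree_path_attribution,
)
from roadrisk.pipeline import training_union


def labelled_table(n=2000, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    x = y + 0.0 if informative else rng.standard_normal(n)
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "region": np.where(np.arange(n) % 2 == 0, "east", "west"),
            "x": x if informative else x,
            "z": rng.standard_normal(n),
            "road_present": y,
        }
    )


def perfect_model():
    """Stump on a feature that IS the response: a perfect classifier."""
    table = labelled_table(informative=True)
    from sklearn.tree import DecisionTreeClassifier
    from roadrisk.forest import ForestModel

    tree = DecisionTreeClassifier(max_depth=1, random_state=0)
    tree.fit(table[["x", "z"]].to_numpy(), table["road_present"])
    return ForestModel(trees=[tree], variables=["x", "z"]), table


def test_perfect_classifier_auc_one():
    model, table = perfect_model()
    report = prevalence_auc(model, table, 4, 300, seed=0, sar_zero=False)
    assert report.auc_mean == 1.0
    assert report.auc_sd == 0.0
    for mean, sd in report.per_region.values():
        assert mean == 1.0 and sd == 0.0


def test_uninformative_scores_near_half():
    """Scores independent of the labels give AUC ~ 0.5 at n = 10,000."""
    model, train_table = perfect_model()
    rng = np.random.default_rng(1)
    fresh = labelled_table(n=10_000, seed=2)
    fresh["x"] = rng.standard_normal(len(fresh))  # decouple scores from labels
    report = prevalence_auc(model, fresh, 1, 5000, seed=0, sar_zero=False)
    assert abs(report.auc_mean - 0.5) < 0.02


def test_report_is_pure_function_and_records_seeds():
    model, table = perfect_model()
    r1 = prevalence_auc(model, table, 5, 200, seed=9, sar_zero=False)
    r2 = prevalence_auc(model, table, 5, 200, seed=9, sar_zero=False)
    assert r1.to_dict() == r2.to_dict()
    assert len(r1.seeds) == 5 and len(set(r1.seeds)) == 5


def test_representativeness_identity_and_offset():
    table = labelled_table(500, seed=3)
    rep = representativeness_report(table, table, ["z"])
    assert rep["abs_gap"].max() == 0.0
    shifted = table.assign(z=table["z"] + 5.0)
    rep2 = representativeness_report(shifted, table, ["z"])
    assert np.allclose(rep2["gap"], 5.0)


def test_training_sample_representative_of_landscape(small_run):
    """Max quantile gap of biophysical covariates, in sd units, stays
    below the pilot-derived bound."""
    table = small_run["table"]
    train = table.loc[training_union(small_run["subsample_sets"])]
    variables = ["slope", "dist_river", "popdens"]
    rep = representativeness_report(train, table, variables)
    for var in variables:
        scale = table[var].std()
        gap = rep.loc[rep["variable"] == var, "abs_gap"].max()
        assert gap / scale < 0.35


def test_compare_frameworks_paired_and_rank_correlated(small_run, small_config):
    tr = small_config.training
    fc = compare_frameworks(
        small_run["table"],
        ["balanced", "original-prevalence", "class-weighted"],
        tr.counts, tr.multiplicities, tr.subsample_presence,
        tr.subsample_absence, tr.trees_per_iteration,
        tr.per_tree_presence, tr.per_tree_absence,
        seed=99, n_eval_iterations=4, n_eval_per_region=600,
    )
    assert sorted(fc.performance["framework"]) == [
        "balanced", "class-weighted", "original-prevalence"
    ]
    assert ((fc.performance["auc_mean"] > 0) & (fc.performance["auc_mean"] <= 1)).all()
    piv = fc.importance.pivot(index="variable", columns="framework", values="mda")
    for alt in ("original-prevalence", "class-weighted"):
        rho = spearmanr(piv["balanced"], piv[alt]).statistic
        assert rho > 0


def test_compare_frameworks_unknown_framework_rejected(small_run, small_config):
    tr = small_config.training
    with pytest.raises(ValueError, match="unknown frameworks"):
        compare_frameworks(
            small_run["table"], ["balanced", "undersampled"],
            tr.counts, tr.multiplicities, tr.subsample_presence,
            tr.subsample_absence, tr.trees_per_iteration,
            tr.per_tree_presence, tr.per_tree_absence, seed=0,
        )


def test_attribution_additivity_and_never_split_zero():
    """Per-record attributions sum to prediction minus base, and a
    variable no tree touches gets exactly zero."""
    model, frame, y = make_stump_model(["x", "z"], "x")
    contrib, base, preds = tree_path_attribution(model, frame)
    np.testing.assert_allclose(contrib.sum(axis=1), preds - base, atol=1e-6)
    zi = model.variables.index("z")
    assert np.abs(contrib[:, zi]).max() == 0.0
    xi = model.variables.index("x")
    assert np.abs(contrib[:, xi]).max() > 0.0


def test_attribution_additivity_on_trained_forest(small_run):
    model = small_run["records"][2].model
    sample = small_run["table"].iloc[:200]
    contrib, base, preds = tree_path_attribution(model, sample)
    np.testing.assert_allclose(contrib.sum(axis=1), preds - base, atol=1e-6)


def test_attribution_selection_overlaps_mda_selection(small_run):
    """The attribution-selected set shares at least half its members with
    the MDA-selected set on the desk study system."""
    kept_attr, _ = shap_selection_variant(
        small_run["records"][1].model,
        small_run["table"],
        small_run["variant_groups"],
        sample=1500,
        seed=3,
    )
    mda_kept = set(small_run["kept_variables"])
    overlap = mda_kept & set(kept_attr)
    assert len(overlap) * 2 >= len(mda_kept)
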