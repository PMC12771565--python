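"""Subsampling, the iteration schedule, and balanced tree draws."""

import numpy as np
import pandas as pd
import pytest

from roadrisk.sampling import (
    IterationPlan,
    build_iteration_plan,
    build_subsamples,
    draw_prevalence_sample,
    draw_tree_sample,
    iteration_pool,
)


def toy_table(n_presence=10, n_absence=20, region="r1"):
    n = n_presence + n_absence
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "region": region,
            "road_present": [1] * n_presence + [0] * n_absence,
        }
    )


def test_partition_mode_is_disjoint_and_exhaustive():
    table = toy_table(10, 20)
    sset = build_subsamples(table, "r1", 5, 10, 2, seed=0, mode="partition")
    a, b = sset.subsamples
    assert len(set(a) & set(b)) == 0
    assert sorted(np.concatenate([a, b])) == list(range(30))
    for sub in (a, b):
        y = table.loc[sub, "road_present"]
        assert int(y.sum()) == 5 and len(y) == 15


def test_partition_shortfall_reports_deficit():
    with pytest.raises(ValueError, match="short 5"):
        build_subsamples(toy_table(10, 30), "r1", 5, 10, 3, seed=0, mode="partition")


def test_resample_mode_allows_reuse():
    sset = build_subsamples(toy_table(10, 30), "r1", 5, 10, 3, seed=0, mode="resample")
    assert len(sset) == 3
    table = toy_table(10, 30)
    for sub in sset.subsamples:
        y = table.loc[sub, "road_present"]
        assert int(y.sum()) == 5 and len(y) == 15


def test_missing_region_and_bad_mode_rejected():
    with pytest.raises(ValueError, match="not present"):
        build_subsamples(toy_table(), "elsewhere", 1, 1, 1, seed=0)
    with pytest.raises(ValueError, match="unknown subsample mode"):
        build_subsamples(toy_table(), "r1", 1, 1, 1, seed=0, mode="bootstrap")


def test_plan_structure_at_published_scale():
    """60/20/10 subsamples close into 60 iterations of 45 trees (2,700
    total); one subsample per region per iteration forces reuse 1/3/6."""
    plan = build_iteration_plan(
        counts={"amazon": 60, "asia_pacific": 20, "congo": 10},
        multiplicities={"amazon": 1, "asia_pacific": 3, "congo": 6},
        trees_per_iteration=45,
        seed=0,
    )
    assert plan.n_iterations == 60
    assert plan.total_trees == 2700
    usage = plan.usage_counts()
    for sid in range(60):
        assert usage[("amazon", sid)] == 1
    for sid in range(20):
        assert usage[("asia_pacific", sid)] == 3
    for sid in range(10):
        assert usage[("congo", sid)] == 6
    assert all(set(it) == {"amazon", "asia_pacific", "congo"} for it in plan.iterations)


def test_plan_degenerate_and_invalid_cases():
    plan = build_iteration_plan({"a": 1, "b": 1}, {"a": 1, "b": 1}, 1, seed=0)
    assert plan.n_iterations == 1
    with pytest.raises(ValueError, match="a: 2, b: 3"):
        build_iteration_plan({"a": 2, "b": 3}, {"a": 1, "b": 1}, 1, seed=0)


def test_plan_is_pure_function_of_seed():
    args = ({"a": 4, "b": 2}, {"a": 1, "b": 2}, 3)
    assert build_iteration_plan(*args, seed=5).iterations == build_iteration_plan(
        *args, seed=5
    ).iterations
    assert build_iteration_plan(*args, seed=5).iterations != build_iteration_plan(
        *args, seed=6
    ).iterations


def test_plan_json_roundtrip(tmp_path):
    plan = build_iteration_plan({"a": 4, "b": 2}, {"a": 1, "b": 2}, 3, seed=9)
    path = tmp_path / "plan.json"
    plan.to_json(path)
    loaded = IterationPlan.from_json(path)
    assert loaded.iterations == plan.iterations
    assert loaded.total_trees == plan.total_trees


def small_plan_setup():
    table = toy_table(3, 3)
    sset = build_subsamples(table, "r1", 3, 3, 1, seed=0, mode="resample")
    plan = build_iteration_plan({"r1": 1}, {"r1": 1}, 1, seed=0)
    return table, {"r1": sset}, plan


def test_tree_draw_exact_balanced_counts_with_replacement():
    """A (5,5) draw from a 3+3 pool is legal with replacement and exact."""
    table, ssets, plan = small_plan_setup()
    draw = draw_tree_sample(plan, 0, table, ssets, 5, 5, seed=1)
    y = table.loc[draw.indices, "road_present"].to_numpy()
    assert len(draw.indices) == 10
    assert int(y.sum()) == 5


def test_tree_draw_zero_count_rejected():
    table, ssets, plan = small_plan_setup()
    with pytest.raises(ValueError, match=">= 1"):
        draw_tree_sample(plan, 0, table, ssets, 0, 5, seed=1)


def test_tree_draw_determinism_contract():
    table, ssets, plan = small_plan_setup()
    d1 = draw_tree_sample(plan, 0, table, ssets, 5, 5, seed=2)
    d2 = draw_tree_sample(plan, 0, table, ssets, 5, 5, seed=2)
    d3 = draw_tree_sample(plan, 0, table, ssets, 5, 5, seed=3)
    np.testing.assert_array_equal(d1.indices, d2.indices)
    assert not np.array_equal(d1.indices, d3.indices)


def test_tree_draw_single_class_pool_rejected():
    table = toy_table(3, 3)
    sset = build_subsamples(table, "r1", 3, 3, 1, seed=0, mode="resample")
    # strip the absences out of the pool
    sset.subsamples[0] = sset.subsamples[0][:3]
    plan = build_iteration_plan({"r1": 1}, {"r1": 1}, 1, seed=0)
    with pytest.raises(ValueError, match="lacks a class"):
        draw_tree_sample(plan, 0, table, {"r1": sset}, 2, 2, seed=0)


def test_iteration_pool_unions_one_subsample_per_region():
    t1 = toy_table(4, 8, "a")
    t2 = toy_table(4, 8, "b")
    t2["cell_id"] += 100
    table = pd.concat([t1, t2], ignore_index=True)
    ssets = {
        r: build_subsamples(table, r, 2, 4, 2, seed=0, mode="partition")
        for r in ("a", "b")
    }
    plan = build_iteration_plan({"a": 2, "b": 2}, {"a": 1, "b": 1}, 1, seed=0)
    pres, absn = iteration_pool(plan, 0, ssets, table)
    assert len(pres) == 4 and len(absn) == 8
    regions = set(table.loc[np.concatenate([pres, absn]), "region"])
    assert regions == {"a", "b"}


def test_prevalence_sample_counts_and_exclusion():
    table = toy_table(30, 70)
    idx = draw_prevalence_sample(table, 50, seed=0)
    y = table.loc[idx, "road_present"]
    assert len(idx) == 50
    assert int(y.sum()) == round(0.3 * 50)
    held = np.arange(0, 10)  # exclude 10 of the presences
    idx2 = draw_prevalence_sample(table, 20, seed=0, exclude=held)
    assert not set(idx2) & set(held)
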