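"""Shared fixtures: a reduced three-region study system and one full
pipeline run over it, reused across the suite to keep runtimes short."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from roadrisk.config import EvalConfig, PipelineConfig, TrainingConfig
from roadrisk.forest import ForestModel
from roadrisk.synthetic import default_study_region, generate_landscape
from roadrisk.workflow import run_pipeline


def small_pipeline_config(master_seed: int = 7) -> PipelineConfig:
    """Desk fixture: the default study system shrunk to 80x80 regions."""
    regions = [
        dataclasses.replace(r, grid_shape=(80, 80))
        for r in default_study_region(master_seed)
    ]
    return PipelineConfig(
        master_seed=master_seed,
        regions=regions,
        training=TrainingConfig(
            counts={"amazonia": 4, "asia_pacific": 2, "congo": 1},
            multiplicities={"amazonia": 1, "asia_pacific": 2, "congo": 4},
            subsample_presence=150,
            subsample_absence=300,
            trees_per_iteration=4,
            per_tree_presence=200,
            per_tree_absence=200,
        ),
        evaluation=EvalConfig(n_iterations=5, n_per_region=800),
        n_eval_per_region_importance=800,
    )


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return small_pipeline_config()


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config.build_regions())


@pytest.fixture(scope="session")
def small_run(small_config):
    """One full pipeline run over the reduced study system."""
    return run_pipeline(small_config)


def make_stump_model(variables, split_variable, threshold=0.0, n_train=200, seed=0):
    """Hand-built one-split forest: presence iff split_variable > threshold.

    A single depth-1 tree trained on perfectly separated data around the
    threshold, wrapped as a ForestModel; an analytically predictable
    oracle for partial dependence, importance and hold-policy tests.
    """
    rng = np.random.default_rng(seed)
    data = {v: rng.standard_normal(n_train) for v in variables}
    x = np.concatenate(
        [
            rng.uniform(threshold + 0.1, threshold + 2.0, n_train // 2),
            rng.uniform(threshold - 2.0, threshold - 0.1, n_train - n_train // 2),
        ]
    )
    data[split_variable] = x
    y = (x > threshold).astype(int)
    frame = pd.DataFrame(data)
    tree = DecisionTreeClassifier(max_depth=1, random_state=0)
    tree.fit(frame[variables].to_numpy(), y)
    return ForestModel(trees=[tree], variables=list(variables)), frame, y
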