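"""Synthetic landscape generator: field structure, road process, impact."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from oracles import morans_null_sd
from roadrisk.spatial import NeighborhoodSpec, morans_i
from roadrisk.synthetic import (
    CovariateSpec,
    RegionSpec,
    distance_grid,
    generate_covariates,
    generate_impact_fine,
    generate_landscape,
    generate_roads,
    default_study_region,
    table_to_grid,
)


def region(covs=(), shape=(50, 50), coefs=None, intercept=0.0, noise_range=0.0,
           noise_sd=0.0, seed=0, name="test"):
    return RegionSpec(
        name=name, grid_shape=shape, covariate_specs=tuple(covs),
        road_coefficients=coefs or {}, intercept=intercept,
        noise_range=noise_range, noise_sd=noise_sd, seed=seed,
    )


def grf_spec(length):
    return CovariateSpec("f", "biophysical", "continuous-GRF",
                         {"correlation_length": length})


def test_spec_validation():
    with pytest.raises(ValueError, match=">= 2"):
        region(shape=(1, 5))
    with pytest.raises(ValueError, match="unknown covariates"):
        region(covs=[grf_spec(1)], coefs={"ghost": 1.0})
    with pytest.raises(ValueError, match="unknown kind"):
        CovariateSpec("x", "political", "continuous-GRF")
    with pytest.raises(ValueError, match=">= 2 classes"):
        CovariateSpec("x", "administrative", "categorical-blocks", {"n_classes": 1})


def test_grf_zero_length_is_iid():
    """Correlation length 0 collapses to per-cell i.i.d. values."""
    table = generate_covariates(region([grf_spec(0)], shape=(20, 20)))
    grid = table_to_grid(table, "test", "f", (20, 20))
    value = morans_i(grid, NeighborhoodSpec("rook", 1))
    sd = morans_null_sd((20, 20), "rook", 1)
    assert abs(value - (-1.0 / 399)) < 3 * sd


def test_grf_long_range_is_autocorrelated():
    """Length-8 fields on 64x64 grids are strongly autocorrelated."""
    for seed in range(5):
        table = generate_covariates(region([grf_spec(8)], shape=(64, 64), seed=seed))
        grid = table_to_grid(table, "test", "f", (64, 64))
        assert morans_i(grid, NeighborhoodSpec("rook", 1)) > 0.2


def test_grf_standardized():
    table = generate_covariates(region([grf_spec(5)], shape=(40, 40)))
    assert table["f"].mean() == pytest.approx(0.0, abs=1e-9)
    assert table["f"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_distance_grid_345_triangle():
    features = np.zeros((10, 10), dtype=bool)
    features[0, 0] = True
    assert distance_grid(features)[3, 4] == 5.0
    with pytest.raises(ValueError, match="empty"):
        distance_grid(np.zeros((3, 3), dtype=bool))


def test_categorical_blocks_are_contiguous_patches():
    spec = CovariateSpec("veg", "administrative", "categorical-blocks", {"n_classes": 5})
    table = generate_covariates(region([spec], shape=(40, 40)))
    grid = table.pivot(index="row", columns="col", values="veg").to_numpy()
    classes = np.unique(grid)
    assert len(classes) >= 2
    for c in classes:
        _, n_components = ndimage.label(grid == c)
        assert n_components == 1


def test_unknown_form_rejected_by_spec():
    with pytest.raises(ValueError, match="unknown form"):
        CovariateSpec("x", "biophysical", "kriged")


def test_generator_determinism():
    """Same seed, bit-identical landscape; different seed differs."""
    specs = default_study_region(3)[:1]
    a = generate_landscape(specs).table
    b = generate_landscape(specs).table
    pd.testing.assert_frame_equal(a, b)
    c = generate_landscape(default_study_region(4)[:1]).table
    assert not a["road_present"].equals(c["road_present"])


def test_covariate_kinds_partition():
    landscape = generate_landscape(default_study_region(0)[:1])
    bio = set(landscape.covariates_of_kind("biophysical"))
    other = set(landscape.covariates_of_kind("socioeconomic", "administrative"))
    assert bio | other == set(landscape.covariates)
    assert not bio & other
    assert other == {"popdens", "gdp", "admin_region", "vegetation_class", "protected_area"}


def test_roads_null_model_prevalence_half():
    spec = region(shape=(100, 100), intercept=0.0)
    table = generate_roads(generate_covariates(spec), spec)
    n = 10_000
    assert abs(table["road_present"].mean() - 0.5) < 3 * np.sqrt(0.25 / n)


def test_roads_saturated_intercept_gives_empty_map():
    spec = region(shape=(100, 100), intercept=-20.0)
    table = generate_roads(generate_covariates(spec), spec)
    assert table["road_present"].sum() == 0


def test_roads_negative_slope_effect():
    """coef -2 on slope: presences sit on flatter ground than absences."""
    spec = region([CovariateSpec("slope", "biophysical", "continuous-GRF",
                                 {"correlation_length": 5})],
                  shape=(200, 200), coefs={"slope": -2.0}, seed=12)
    table = generate_roads(generate_covariates(spec), spec)
    pres = table.loc[table.road_present == 1, "slope"].mean()
    absn = table.loc[table.road_present == 0, "slope"].mean()
    assert pres < absn


def test_road_prevalence_monotone_in_intercept():
    prevs = []
    for intercept in (-2.0, 0.0, 2.0):
        spec = region([grf_spec(4)], shape=(60, 60), coefs={"f": 1.0},
                      intercept=intercept, noise_range=3, noise_sd=0.5, seed=5)
        table = generate_roads(generate_covariates(spec), spec)
        prevs.append(table["road_present"].mean())
    assert prevs[0] < prevs[1] < prevs[2]


def test_impact_fine_structure_and_limits():
    spec = region(shape=(30, 30), intercept=0.0)
    table = generate_roads(generate_covariates(spec), spec)
    fine = generate_impact_fine(table, gamma_road=0.0, gamma_base=-30.0, seed=0)
    assert fine.flags.shape == (len(table), 16)
    assert fine.flags.sum() == 0


def test_impact_concentrates_near_roads():
    spec = region(shape=(60, 60), intercept=0.0, seed=3)
    table = generate_roads(generate_covariates(spec), spec)
    fine = generate_impact_fine(table, gamma_road=5.0, gamma_base=-4.0, seed=1)
    frac = fine.flags.mean(axis=1)
    road = table["road_present"].to_numpy() == 1
    assert frac[road].mean() > frac[~road].mean()


def test_impact_requires_roads():
    spec = region(shape=(10, 10))
    with pytest.raises(ValueError, match="road_present"):
        generate_impact_fine(generate_covariates(spec), 1.0, -1.0, seed=0)


def test_landscape_cell_ids_unique_and_prevalences_differ():
    landscape = generate_landscape(default_study_region(0))
    assert landscape.table["cell_id"].is_unique
    prevs = sorted(landscape.road_prevalence.values())
    assert prevs[0] < prevs[-1]
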