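"""Synthetic multi-region landscapes for road and impact modelling.

The generator emulates the statistical structure of a tropical road-risk
study system on an abstract planar grid of 1-ha cells:

* spatially autocorrelated continuous covariates (stationary Gaussian
  random fields: slope, roughness, soil fractions, rainfall seasonality,
  population density, GDP),
* contiguous categorical/administrative covariates (nearest-seed block
  partitions: administrative region, vegetation class, protected-area
  class),
* distance-to-feature covariates (exact Euclidean distance in cell units
  to a seeded random feature set, e.g. rivers),
* a road-generating process that is Bernoulli with a logistic link over
  standardized covariates plus spatially correlated noise, and
* a fine-scale (25 m; 4x4 subcells per 1-ha cell) human-impact layer
  concentrated near roads.

Everything is a pure function of its spec and seed: same seed, same
landscape, bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .seeds import derive_seed

__all__ = [
    "CovariateSpec",
    "RegionSpec",
    "Landscape",
    "FineImpactGrid",
    "generate_covariates",
    "generate_roads",
    "generate_impact_fine",
    "generate_landscape",
    "default_study_region",
    "table_to_grid",
    "distance_grid",
]

KINDS = ("biophysical", "socioeconomic", "administrative")
FORMS = ("continuous-GRF", "categorical-blocks", "distance-to-feature")


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate: its name, thematic kind and generative form.

    ``params`` is form-specific: ``correlation_length`` (cells) for GRFs,
    ``n_classes`` for categorical blocks, ``density`` (feature cells per
    cell) for distance-to-feature.
    """

    name: str
    kind: str
    form: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.form not in FORMS:
            raise ValueError(f"covariate {self.name!r}: unknown form {self.form!r}")
        if self.form == "categorical-blocks" and self.params.get("n_classes", 0) < 2:
            raise ValueError(
                f"categorical covariate {self.name!r} must declare >= 2 classes"
            )


@dataclass(frozen=True)
class RegionSpec:
    """One region of the synthetic study system.

    ``road_coefficients`` are logistic effects on *standardized* covariate
    values (z-scored continuous values; z-scored class codes for
    categorical covariates), so effect sizes are comparable across
    covariates.  ``noise_range``/``noise_sd`` parameterise the spatially
    correlated Gaussian noise added to the road linear predictor.
    """

    name: str
    grid_shape: tuple
    covariate_specs: tuple
    road_coefficients: dict
    intercept: float
    noise_range: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 2 or cols < 2:
            raise ValueError(f"region {self.name!r}: grid dimensions must be >= 2")
        names = {c.name for c in self.covariate_specs}
        unknown = set(self.road_coefficients) - names
        if unknown:
            raise ValueError(
                f"region {self.name!r}: road coefficients for unknown covariates "
                f"{sorted(unknown)}"
            )
        if self.noise_range < 0 or self.noise_sd < 0:
            raise ValueError("noise_range and noise_sd must be >= 0")


@dataclass
class FineImpactGrid:
    """25-m human-impact flags: 16 subcells (4x4) per 1-ha cell."""

    cell_ids: np.ndarray
    flags: np.ndarray  # shape (n_cells, 16), values in {0, 1}

    def __post_init__(self) -> None:
        if self.flags.ndim != 2 or self.flags.shape[1] != 16:
            raise ValueError("fine impact grid must have exactly 16 subcells per cell")
        if len(self.cell_ids) != len(self.flags):
            raise ValueError("cell_ids and flags must align")


@dataclass
class Landscape:
    """A multi-region landscape table plus its covariate metadata.

    ``table`` is long-format, one row per 1-ha cell: cell_id, region,
    row, col, covariate columns and (once generated) road_present /
    impact columns.  ``kinds``/``forms`` map covariate name to its
    thematic kind and generative form; ``grid_shapes`` maps region name
    to (rows, cols).
    """

    table: pd.DataFrame
    kinds: dict
    forms: dict
    grid_shapes: dict
    road_prevalence: dict = field(default_factory=dict)

    @property
    def covariates(self) -> list:
        return list(self.kinds)

    def covariates_of_kind(self, *kinds: str) -> list:
        return [c for c, k in self.kinds.items() if k in kinds]

    def grid(self, region: str, column: str) -> np.ndarray:
        return table_to_grid(self.table, region, column, self.grid_shapes[region])


def table_to_grid(
    table: pd.DataFrame, region: str, column: str, shape: tuple
) -> np.ndarray:
    """Reshape one region's cell column onto its (rows, cols) grid."""
    sub = table[table["region"] == region]
    grid = np.empty(shape, dtype=float)
    grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub[column].to_numpy(float)
    return grid


def _grf(shape: tuple, correlation_length: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Gaussian random field, standardized to mean 0, sd 1.

    Kernel-smoothed white noise on a torus (wrap boundary) keeps the
    field stationary; the Gaussian smoothing scale is the correlation
    length in cells.  Length 0 degenerates to i.i.d. noise.
    """
    white = rng.standard_normal(shape)
    if correlation_length > 0:
        f = ndimage.gaussian_filter(white, sigma=correlation_length, mode="wrap")
    else:
        f = white
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _categorical_blocks(
    shape: tuple, n_classes: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous patch partition: nearest of n_classes seed cells."""
    rows, cols = shape
    seeds_r = rng.uniform(0, rows, size=n_classes)
    seeds_c = rng.uniform(0, cols, size=n_classes)
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1)


def distance_grid(features: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance (cell units, cell centres) to the nearest
    True cell of ``features``; the synthetic world is planar, no geodesy."""
    features = np.asarray(features, dtype=bool)
    if not features.any():
        raise ValueError("feature set is empty")
    return ndimage.distance_transform_edt(~features)


def _distance_to_feature(
    shape: tuple, density: float, rng: np.random.Generator
) -> np.ndarray:
    """Distance to a seeded random feature set (at least one feature cell)."""
    features = rng.random(shape) < density
    if not features.any():
        features[rng.integers(shape[0]), rng.integers(shape[1])] = True
    return distance_grid(features)


def generate_covariates(spec: RegionSpec) -> pd.DataFrame:
    """Realize one region's covariate table (responses unset).

    Continuous-GRF covariates are stationary Gaussian fields at the
    declared correlation length, standardized to mean 0 / sd 1;
    categorical-blocks covariates partition the grid into contiguous
    patches labelled ``c0..c{K-1}``; distance-to-feature covariates are
    Euclidean distances in cell units to a seeded random feature set.
    """
    rows, cols = spec.grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    data = {
        "cell_id": np.arange(rows * cols),
        "region": spec.name,
        "row": rr.ravel(),
        "col": cc.ravel(),
    }
    for cov in spec.covariate_specs:
        rng = np.random.default_rng(derive_seed(spec.seed, "cov", cov.name))
        if cov.form == "continuous-GRF":
            field_ = _grf(spec.grid_shape, cov.params.get("correlation_length", 0.0), rng)
            data[cov.name] = field_.ravel()
        elif cov.form == "categorical-blocks":
            codes = _categorical_blocks(spec.grid_shape, cov.params["n_classes"], rng)
            data[cov.name] = np.array([f"c{k}" for k in codes.ravel()])
        elif cov.form == "distance-to-feature":
            dist = _distance_to_feature(
                spec.grid_shape, cov.params.get("density", 0.001), rng
            )
            data[cov.name] = dist.ravel()
        else:  # pragma: no cover - guarded by CovariateSpec
            raise ValueError(f"unknown form for covariate {cov.name!r}")
    return pd.DataFrame(data)


def _standardized_effect_column(
    table: pd.DataFrame, cov: CovariateSpec
) -> np.ndarray:
    """Numeric, z-scored version of a covariate for the road linear predictor.

    Categorical classes enter through their z-scored integer codes, so a
    nonzero coefficient makes classes differ systematically in road
    propensity.
    """
    if cov.form == "categorical-blocks":
        x = table[cov.name].str.removeprefix("c").to_numpy(int).astype(float)
    else:
        x = table[cov.name].to_numpy(float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_roads(table: pd.DataFrame, spec: RegionSpec) -> pd.DataFrame:
    """Set road presence from the logistic covariate model plus GRF noise.

    road ~ Bernoulli(sigmoid(intercept + sum coef * z(covariate) + u)),
    with u a Gaussian random field of the spec's noise_range, scaled to
    sd noise_sd.  The realized prevalence is stored in
    ``table.attrs["road_prevalence"]``.
    """
    cov_by_name = {c.name: c for c in spec.covariate_specs}
    eta = np.full(len(table), spec.intercept, dtype=float)
    for name, coef in spec.road_coefficients.items():
        if coef != 0.0:
            eta += coef * _standardized_effect_column(table, cov_by_name[name])
    if spec.noise_sd > 0:
        rng_u = np.random.default_rng(derive_seed(spec.seed, "road-noise"))
        u = _grf(spec.grid_shape, spec.noise_range, rng_u) * spec.noise_sd
        eta += u.ravel()[table["cell_id"].to_numpy() % (spec.grid_shape[0] * spec.grid_shape[1])]
    p = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(derive_seed(spec.seed, "roads"))
    out = table.copy()
    out["road_present"] = (rng.random(len(table)) < p).astype(np.int8)
    prevalence = float(out["road_present"].mean())
    out.attrs = dict(table.attrs)
    out.attrs.setdefault("road_prevalence", {})[spec.name] = prevalence
    return out


def generate_impact_fine(
    table: pd.DataFrame, gamma_road: float, gamma_base: float, seed: int
) -> FineImpactGrid:
    """Realize the 25-m human-impact layer.

    Each of the 16 subcells of a 1-ha cell is impacted independently with
    probability sigmoid(gamma_base + gamma_road * road_present(parent)),
    concentrating impact near roads for positive gamma_road.
    """
    if "road_present" not in table.columns:
        raise ValueError("road_present must be generated before the impact layer")
    road = table["road_present"].to_numpy()
    p = 1.0 / (1.0 + np.exp(-(gamma_base + gamma_road * road)))
    rng = np.random.default_rng(seed)
    flags = (rng.random((len(table), 16)) < p[:, None]).astype(np.int8)
    return FineImpactGrid(cell_ids=table["cell_id"].to_numpy().copy(), flags=flags)


def generate_landscape(
    specs: list[RegionSpec],
    impact_gamma_road: float | None = None,
    impact_gamma_base: float | None = None,
    seed: int | None = None,
) -> Landscape:
    """Generate a multi-region landscape (covariates + roads, optional impact).

    Cell ids are made globally unique by offsetting per region.  When the
    impact gammas are given, the fine grid is generated and aggregation
    is left to the impact module.
    """
    frames = []
    prevalence = {}
    offset = 0
    kinds: dict = {}
    forms: dict = {}
    shapes: dict = {}
    for spec in specs:
        t = generate_covariates(spec)
        t = generate_roads(t, spec)
        prevalence[spec.name] = t.attrs["road_prevalence"][spec.name]
        t["cell_id"] = t["cell_id"] + offset
        offset += spec.grid_shape[0] * spec.grid_shape[1]
        frames.append(t)
        shapes[spec.name] = tuple(spec.grid_shape)
        for cov in spec.covariate_specs:
            kinds[cov.name] = cov.kind
            forms[cov.name] = cov.form
    table = pd.concat(frames, ignore_index=True)
    table.index = pd.RangeIndex(len(table))
    return Landscape(
        table=table,
        kinds=kinds,
        forms=forms,
        grid_shapes=shapes,
        road_prevalence=prevalence,
    )


def default_study_region(master_seed: int = 0) -> list[RegionSpec]:
    """Three-region desk-scale study system (200x200 cells each).

    Regions mirror the unequal-prevalence structure of a pantropical
    study: a large high-prevalence region, an intermediate one, and a
    sparse one.  Road coefficients act on standardized covariates; two
    pure-noise fields (zero coefficient) are included so recovery of the
    causal set is checkable.  Population density is deliberately more
    influential in the sparse region.
    """
    covs = (
        CovariateSpec("slope", "biophysical", "continuous-GRF", {"correlation_length": 10}),
        CovariateSpec("roughness", "biophysical", "continuous-GRF", {"correlation_length": 6}),
        CovariateSpec("silt_fraction", "biophysical", "continuous-GRF", {"correlation_length": 12}),
        CovariateSpec(
            "rainfall_seasonality", "biophysical", "continuous-GRF", {"correlation_length": 20}
        ),
        CovariateSpec("dist_river", "biophysical", "distance-to-feature", {"density": 0.002}),
        CovariateSpec("popdens", "socioeconomic", "continuous-GRF", {"correlation_length": 15}),
        CovariateSpec("gdp", "socioeconomic", "continuous-GRF", {"correlation_length": 25}),
        CovariateSpec("admin_region", "administrative", "categorical-blocks", {"n_classes": 6}),
        CovariateSpec("vegetation_class", "administrative", "categorical-blocks", {"n_classes": 4}),
        CovariateSpec("protected_area", "administrative", "categorical-blocks", {"n_classes": 3}),
        CovariateSpec("noise_a", "biophysical", "continuous-GRF", {"correlation_length": 8}),
        CovariateSpec("noise_b", "biophysical", "continuous-GRF", {"correlation_length": 8}),
    )
    base_coefs = {
        "slope": -1.0,
        "roughness": -0.6,
        "silt_fraction": 0.8,
        "rainfall_seasonality": -0.7,
        "dist_river": -1.2,
        "popdens": 1.0,
        "gdp": 0.6,
        "admin_region": 0.6,
        "vegetation_class": 0.6,
        "protected_area": -0.8,
    }
    regions = []
    for name, intercept, pop_coef in (
        ("amazonia", -0.5, 0.8),
        ("asia_pacific", -1.0, 0.9),
        ("congo", -1.5, 1.3),
    ):
        coefs = dict(base_coefs)
        coefs["popdens"] = pop_coef
        regions.append(
            RegionSpec(
                name=name,
                grid_shape=(200, 200),
                covariate_specs=covs,
                road_coefficients=coefs,
                intercept=intercept,
                noise_range=6.0,
                noise_sd=1.0,
                seed=derive_seed(master_seed, "region", name),
            )
        )
    return regions
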