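"""Pipeline configuration.

One YAML document (or :class:`PipelineConfig` instance) fixes the whole
run: the synthetic study region, subsample counts and reuse
multiplicities, per-tree draw sizes, tree hyperparameters, the SAR
neighbourhood, focal-variant radii, impact-layer parameters, evaluation
settings and the single master seed from which every stage seed derives.
The config validates before any stage runs; its canonical hash stamps
every artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .spatial import NeighborhoodSpec
from .synthetic import CovariateSpec, RegionSpec, default_study_region

__all__ = ["TrainingConfig", "ImpactConfig", "EvalConfig", "PipelineConfig"]


@dataclass
class TrainingConfig:
    """Sampling and forest-size parameters shared by road and impact models.

    Desk-scale defaults mirror the full-scale design's structure: a large
    region whose subsamples are used once, an intermediate one used
    twice, and a sparse one used six times, with products equal so the
    plan closes.
    """

    counts: dict = field(
        default_factory=lambda: {"amazonia": 6, "asia_pacific": 3, "congo": 1}
    )
    multiplicities: dict = field(
        default_factory=lambda: {"amazonia": 1, "asia_pacific": 2, "congo": 6}
    )
    subsample_presence: int = 500
    subsample_absence: int = 1000
    trees_per_iteration: int = 5
    per_tree_presence: int = 400
    per_tree_absence: int = 400
    mode: str = "partition"
    tree_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.counts) != set(self.multiplicities):
            raise ValueError("counts and multiplicities must cover the same regions")
        products = {
            r: self.counts[r] * self.multiplicities[r] for r in self.counts
        }
        if len(set(products.values())) != 1:
            raise ValueError(
                "counts x multiplicities must agree across regions: "
                + ", ".join(f"{r}: {p}" for r, p in sorted(products.items()))
            )
        for name in (
            "subsample_presence", "subsample_absence", "trees_per_iteration",
            "per_tree_presence", "per_tree_absence",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ImpactConfig:
    """Fine-scale impact generation and aggregation parameters."""

    gamma_base: float = -4.0
    gamma_road: float = 5.0
    threshold: float = 0.10

    def validate(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("impact threshold must be in (0, 1]")


@dataclass
class EvalConfig:
    """Prevalence-ratio evaluation settings."""

    n_iterations: int = 25
    n_per_region: int = 2000

    def validate(self) -> None:
        if self.n_iterations < 1 or self.n_per_region < 2:
            raise ValueError("evaluation sizes too small")


@dataclass
class PipelineConfig:
    """Everything a full run needs, keyed to one master seed."""

    master_seed: int = 0
    regions: list | None = None  # None -> default_study_region(master_seed)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    impact: ImpactConfig = field(default_factory=ImpactConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    neighborhood_scheme: str = "queen"
    neighborhood_radius: int = 1
    focal_variants: dict = field(default_factory=lambda: {"popdens": [3, 8]})
    n_importance_reps: int = 3
    n_eval_per_region_importance: int = 2000

    def validate(self) -> None:
        self.training.validate()
        self.impact.validate()
        self.evaluation.validate()
        NeighborhoodSpec(self.neighborhood_scheme, self.neighborhood_radius)
        region_names = {r.name for r in self.build_regions()}
        if set(self.training.counts) != region_names:
            raise ValueError(
                "training counts must cover exactly the configured regions: "
                f"{sorted(region_names)}"
            )

    def build_regions(self) -> list:
        if self.regions is None:
            return default_study_region(self.master_seed)
        return list(self.regions)

    def neighborhood(self) -> NeighborhoodSpec:
        return NeighborhoodSpec(self.neighborhood_scheme, self.neighborhood_radius)

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "master_seed": self.master_seed,
            "training": asdict(self.training),
            "impact": asdict(self.impact),
            "evaluation": asdict(self.evaluation),
            "neighborhood_scheme": self.neighborhood_scheme,
            "neighborhood_radius": self.neighborhood_radius,
            "focal_variants": {k: list(v) for k, v in self.focal_variants.items()},
            "n_importance_reps": self.n_importance_reps,
            "n_eval_per_region_importance": self.n_eval_per_region_importance,
        }
        if self.regions is not None:
            d["regions"] = [_region_to_dict(r) for r in self.regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(
            master_seed=d.get("master_seed", 0),
            regions=(
                [_region_from_dict(r) for r in d["regions"]]
                if "regions" in d
                else None
            ),
            training=TrainingConfig(**d.get("training", {})),
            impact=ImpactConfig(**d.get("impact", {})),
            evaluation=EvalConfig(**d.get("evaluation", {})),
            neighborhood_scheme=d.get("neighborhood_scheme", "queen"),
            neighborhood_radius=d.get("neighborhood_radius", 1),
            focal_variants=d.get("focal_variants", {"popdens": [3, 8]}),
            n_importance_reps=d.get("n_importance_reps", 3),
            n_eval_per_region_importance=d.get("n_eval_per_region_importance", 2000),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text) -> "PipelineConfig":
        try:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(path_or_text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _region_to_dict(r: RegionSpec) -> dict:
    return {
        "name": r.name,
        "grid_shape": list(r.grid_shape),
        "covariates": [
            {"name": c.name, "kind": c.kind, "form": c.form, "params": dict(c.params)}
            for c in r.covariate_specs
        ],
        "road_coefficients": dict(r.road_coefficients),
        "intercept": r.intercept,
        "noise_range": r.noise_range,
        "noise_sd": r.noise_sd,
        "seed": r.seed,
    }


def _region_from_dict(d: dict) -> RegionSpec:
    return RegionSpec(
        name=d["name"],
        grid_shape=tuple(d["grid_shape"]),
        covariate_specs=tuple(
            CovariateSpec(c["name"], c["kind"], c["form"], dict(c.get("params", {})))
            for c in d["covariates"]
        ),
        road_coefficients=dict(d.get("road_coefficients", {})),
        intercept=float(d.get("intercept", 0.0)),
        noise_range=float(d.get("noise_range", 0.0)),
        noise_sd=float(d.get("noise_sd", 0.0)),
        seed=int(d.get("seed", 0)),
    )
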