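"""The road expansion risk index.

The index is the final model's predicted probability of road presence
computed from biophysical suitability alone: socioeconomic and
administrative inputs are overwritten with a fixed policy value (their
training mean, or zero for rank-encoded classes), the SAR term is held
at 0, and the resulting raw surface is rescaled so that the
sensitivity+specificity-maximising threshold maps to 0.5, the surface
minimum to 0 and the maximum to 1.  A cell above 0.5 is therefore more
likely than not to suit a road on biophysical grounds, regardless of who
currently lives or governs there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import ForestModel, predict_proba
from .pipeline import SAR_TERM

__all__ = [
    "HoldSpec",
    "RiskSurface",
    "partial_prediction_surface",
    "find_threshold",
    "rescale_to_risk",
    "build_risk_surface",
]

POLICIES = ("mean", "zero", "free")


def base_covariate(name: str) -> str:
    """Strip derived-variable suffixes (__rank*, _f<r>) to the base name."""
    base = name.split("__rank")[0]
    parts = base.rsplit("_f", 1)
    if len(parts) == 2 and parts[1].isdigit():
        base = parts[0]
    return base


@dataclass
class HoldSpec:
    """Per-variable hold policy for the partial prediction surface.

    Biophysical variables stay ``free``; socioeconomic and administrative
    variables are pinned at their training ``mean`` or at ``zero`` (zero
    being "below every observed class" for rank-encoded variables); the
    SAR term is always held at 0.
    """

    policies: dict = field(default_factory=dict)
    means: dict | None = None  # frozen training means for "mean" policies

    def freeze_means(self, reference: pd.DataFrame) -> "HoldSpec":
        """Pin every "mean" policy to the reference (training) sample's
        column means, making the surface independent of later inputs."""
        means = {
            v: float(reference[v].astype(float).mean())
            for v, p in self.policies.items()
            if p == "mean"
        }
        return HoldSpec(dict(self.policies), means)

    def validate(self, variables: list) -> None:
        missing = [v for v in variables if v not in self.policies]
        if missing:
            raise ValueError(f"hold policy missing for variables: {missing}")
        bad = {v: p for v, p in self.policies.items() if p not in POLICIES}
        if bad:
            raise ValueError(f"unknown hold policies: {bad}")
        if self.policies.get(SAR_TERM, "zero") != "zero":
            raise ValueError("the SAR term must be held at zero")

    @classmethod
    def from_kinds(cls, variables: list, kinds: dict) -> "HoldSpec":
        """Default policy from covariate kinds.

        Continuous socioeconomic covariates are held at their mean (zero
        is meaningless for a standardized density); administrative
        rank-encoded covariates at zero; biophysical covariates free.
        """
        policies = {}
        for v in variables:
            if v == SAR_TERM:
                policies[v] = "zero"
                continue
            kind = kinds.get(base_covariate(v))
            if kind == "biophysical":
                policies[v] = "free"
            elif kind == "socioeconomic":
                policies[v] = "mean"
            elif kind == "administrative":
                policies[v] = "zero"
            else:
                raise ValueError(f"unknown covariate kind for variable {v!r}")
        return cls(policies)


@dataclass
class RiskSurface:
    """Rescaled road-expansion-risk values with their anchor points."""

    values: np.ndarray
    threshold_raw: float
    min_raw: float
    max_raw: float


def partial_prediction_surface(
    model: ForestModel,
    table: pd.DataFrame,
    hold: HoldSpec,
    means_from: pd.DataFrame | None = None,
) -> np.ndarray:
    """Predict road presence with held variables overwritten per policy.

    ``mean`` policies use, in order of precedence: means frozen on the
    HoldSpec (see :meth:`HoldSpec.freeze_means`), column means of
    ``means_from`` (the training sample), or of ``table`` itself.  With
    frozen or external means the output is fully independent of the
    table's values for every held variable.
    """
    hold.validate(model.variables)
    ref = means_from if means_from is not None else table
    work = table.copy()
    for var in model.variables:
        policy = hold.policies[var]
        if policy == "mean":
            if hold.means is not None and var in hold.means:
                work[var] = hold.means[var]
            else:
                work[var] = float(ref[var].astype(float).mean())
        elif policy == "zero":
            work[var] = 0.0
    return predict_proba(model, work)


def find_threshold(labels: np.ndarray, raw_scores: np.ndarray) -> float:
    """Score cut-off maximising sensitivity + specificity.

    Candidates are the observed unique raw scores (vote fractions form a
    finite grid); classification is presence <=> score >= t; ties in the
    objective break toward the smallest threshold.
    """
    labels = np.asarray(labels)
    scores = np.asarray(raw_scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("threshold search requires both classes present")
    candidates = np.unique(scores)
    # sensitivity(t) = P(score >= t | y=1); specificity(t) = P(score < t | y=0)
    pos_scores = np.sort(scores[labels == 1])
    neg_scores = np.sort(scores[labels == 0])
    sens = 1.0 - np.searchsorted(pos_scores, candidates, side="left") / n_pos
    spec = np.searchsorted(neg_scores, candidates, side="left") / n_neg
    objective = sens + spec
    best = np.flatnonzero(objective == objective.max())[0]  # smallest candidate
    return float(candidates[best])


def rescale_to_risk(
    raw_scores: np.ndarray,
    threshold_raw: float,
    min_raw: float | None = None,
    max_raw: float | None = None,
) -> RiskSurface:
    """Two-segment piecewise-linear rescale anchored at three points.

    [min_raw, threshold_raw] maps onto [0, 0.5] and
    [threshold_raw, max_raw] onto [0.5, 1], so the optimal classification
    threshold of the raw surface sits exactly at risk 0.5.  A degenerate
    half-interval (threshold at the min or max) maps that endpoint to 0.5
    with a warning.
    """
    raw = np.asarray(raw_scores, dtype=float)
    lo = float(raw.min()) if min_raw is None else float(min_raw)
    hi = float(raw.max()) if max_raw is None else float(max_raw)
    t = float(threshold_raw)
    if lo >= hi:
        raise ValueError("constant raw surface: min_raw must be < max_raw")
    if not lo <= t <= hi:
        raise ValueError("threshold_raw must lie within [min_raw, max_raw]")
    values = np.empty_like(raw)
    lower = raw <= t
    if t == lo:
        warnings.warn("threshold at surface minimum; lower segment degenerate")
        values[lower] = 0.5
    else:
        values[lower] = 0.5 * (raw[lower] - lo) / (t - lo)
    if t == hi:
        if t != lo:
            warnings.warn("threshold at surface maximum; upper segment degenerate")
        values[~lower] = 0.5
    else:
        values[~lower] = 0.5 + 0.5 * (raw[~lower] - t) / (hi - t)
    values = np.clip(values, 0.0, 1.0)
    return RiskSurface(values=values, threshold_raw=t, min_raw=lo, max_raw=hi)


def build_risk_surface(
    model: ForestModel,
    table: pd.DataFrame,
    hold: HoldSpec,
    response: str = "road_present",
    means_from: pd.DataFrame | None = None,
) -> RiskSurface:
    """Full risk-index construction: partial surface, threshold, rescale."""
    raw = partial_prediction_surface(model, table, hold, means_from=means_from)
    threshold = find_threshold(table[response].to_numpy(), raw)
    return rescale_to_risk(raw, threshold)
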