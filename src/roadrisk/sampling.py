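"""Region-balanced subsampling and the iteration schedule.

The training design divides each region's cells into subsamples with
fixed presence/absence counts, then schedules iterations so that every
iteration trains on exactly one subsample per region.  Regions with fewer
subsamples reuse each of them a fixed number of times (the multiplicity),
so each region contributes the same amount of training exposure despite
unequal data volumes.  Individual trees are then trained on balanced
bootstrap draws (fixed presence and absence counts, with replacement)
from the iteration's pooled subsamples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seeds import derive_seed

__all__ = [
    "SubsampleSet",
    "IterationPlan",
    "TreeDraw",
    "build_subsamples",
    "build_iteration_plan",
    "draw_tree_sample",
    "iteration_pool",
    "draw_prevalence_sample",
]


@dataclass
class SubsampleSet:
    """Fixed-count subsamples of one region's cells.

    ``subsamples[i]`` is an array of table index labels containing exactly
    ``n_presence`` presences followed by ``n_absence`` absences.  In
    partition mode the subsamples are pairwise disjoint.
    """

    region: str
    subsamples: list
    n_presence: int
    n_absence: int
    mode: str
    response: str
    seed: int

    def __len__(self) -> int:
        return len(self.subsamples)


@dataclass
class TreeDraw:
    """One tree's balanced bootstrap training draw (index multiset)."""

    iteration_id: int
    indices: np.ndarray
    n_presence: int
    n_absence: int
    seed: int


@dataclass
class IterationPlan:
    """Schedule mapping each training iteration to one subsample per region.

    Every region-subsample appears exactly ``multiplicities[region]`` times
    across the plan, and counts[r] * multiplicities[r] is the common number
    of iterations.
    """

    iterations: list  # list of {region: subsample_id}
    trees_per_iteration: int
    counts: dict
    multiplicities: dict
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def total_trees(self) -> int:
        return self.n_iterations * self.trees_per_iteration

    def usage_counts(self) -> dict:
        """Observed (region, subsample_id) usage across the plan."""
        usage: dict = {}
        for it in self.iterations:
            for region, sid in it.items():
                usage[(region, sid)] = usage.get((region, sid), 0) + 1
        return usage

    def to_json(self, path=None) -> str:
        payload = {
            "iterations": [
                {r: int(s) for r, s in it.items()} for it in self.iterations
            ],
            "trees_per_iteration": self.trees_per_iteration,
            "counts": {r: int(c) for r, c in self.counts.items()},
            "multiplicities": {r: int(m) for r, m in self.multiplicities.items()},
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "IterationPlan":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            iterations=payload["iterations"],
            trees_per_iteration=payload["trees_per_iteration"],
            counts=payload["counts"],
            multiplicities=payload["multiplicities"],
            seed=payload["seed"],
        )


def build_subsamples(
    table: pd.DataFrame,
    region: str,
    n_presence: int,
    n_absence: int,
    n_subsamples: int,
    seed: int,
    mode: str = "partition",
    response: str = "road_present",
) -> SubsampleSet:
    """Divide one region's cells into subsamples of fixed class counts.

    ``partition`` mode (default) assigns records without replacement
    across subsamples, so they are pairwise disjoint; it errors if the
    region lacks the required presences or absences, reporting the
    shortfall.  ``resample`` mode draws each subsample independently
    (without replacement within a subsample when the pool allows), for
    small pools that cannot support a partition.
    """
    if mode not in ("partition", "resample"):
        raise ValueError(f"unknown subsample mode {mode!r}")
    if n_presence < 1 or n_absence < 1 or n_subsamples < 1:
        raise ValueError("subsample counts must be positive")
    sub = table[table["region"] == region]
    if len(sub) == 0:
        raise ValueError(f"region {region!r} not present in table")
    y = sub[response].to_numpy()
    pres_idx = sub.index.to_numpy()[y == 1]
    abs_idx = sub.index.to_numpy()[y == 0]
    rng = np.random.default_rng(seed)

    subsamples = []
    if mode == "partition":
        need_p = n_presence * n_subsamples
        need_a = n_absence * n_subsamples
        if len(pres_idx) < need_p or len(abs_idx) < need_a:
            raise ValueError(
                f"region {region!r} cannot be partitioned: need {need_p} presences "
                f"(have {len(pres_idx)}, short {max(0, need_p - len(pres_idx))}) and "
                f"{need_a} absences (have {len(abs_idx)}, short "
                f"{max(0, need_a - len(abs_idx))})"
            )
        pres_perm = rng.permutation(pres_idx)
        abs_perm = rng.permutation(abs_idx)
        for i in range(n_subsamples):
            p = pres_perm[i * n_presence : (i + 1) * n_presence]
            a = abs_perm[i * n_absence : (i + 1) * n_absence]
            subsamples.append(np.concatenate([p, a]))
    else:
        for i in range(n_subsamples):
            p = rng.choice(pres_idx, size=n_presence, replace=len(pres_idx) < n_presence)
            a = rng.choice(abs_idx, size=n_absence, replace=len(abs_idx) < n_absence)
            subsamples.append(np.concatenate([p, a]))

    return SubsampleSet(
        region=region,
        subsamples=subsamples,
        n_presence=n_presence,
        n_absence=n_absence,
        mode=mode,
        response=response,
        seed=seed,
    )


def build_iteration_plan(
    counts: dict,
    multiplicities: dict,
    trees_per_iteration: int,
    seed: int,
) -> IterationPlan:
    """Assemble the iteration schedule honouring reuse multiplicities.

    Requires counts[r] * multiplicities[r] to be identical across regions;
    that product is the number of iterations.  The pairing of subsamples
    across regions is a seeded random assignment (each region's subsample
    ids, replicated by multiplicity, are independently shuffled and dealt
    out one per iteration), so every region-subsample is used exactly its
    multiplicity across the plan.
    """
    if set(counts) != set(multiplicities):
        raise ValueError("counts and multiplicities must cover the same regions")
    if trees_per_iteration < 1:
        raise ValueError("trees_per_iteration must be >= 1")
    products = {r: counts[r] * multiplicities[r] for r in counts}
    if len(set(products.values())) != 1:
        raise ValueError(
            "counts x multiplicities must be equal across regions; got "
            + ", ".join(f"{r}: {p}" for r, p in sorted(products.items()))
        )
    n_iter = next(iter(products.values()))
    iterations = [dict() for _ in range(n_iter)]
    for region in sorted(counts):
        ids = np.repeat(np.arange(counts[region]), multiplicities[region])
        rng = np.random.default_rng(derive_seed(seed, "plan", region))
        for it, sid in zip(iterations, rng.permutation(ids)):
            it[region] = int(sid)
    return IterationPlan(
        iterations=iterations,
        trees_per_iteration=trees_per_iteration,
        counts=dict(counts),
        multiplicities=dict(multiplicities),
        seed=seed,
    )


def iteration_pool(
    plan: IterationPlan,
    iteration_id: int,
    subsample_sets: dict,
    table: pd.DataFrame,
    response: str = "road_present",
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (presence indices, absence indices) for one iteration.

    The pool is the union (as a concatenated multiset) of the iteration's
    one subsample per region.
    """
    if not 0 <= iteration_id < plan.n_iterations:
        raise ValueError(f"iteration {iteration_id} outside plan of {plan.n_iterations}")
    assignment = plan.iterations[iteration_id]
    parts = []
    for region in sorted(assignment):
        sset = subsample_sets[region]
        parts.append(np.asarray(sset.subsamples[assignment[region]]))
    pool = np.concatenate(parts)
    y = table.loc[pool, response].to_numpy()
    return pool[y == 1], pool[y == 0]


def draw_tree_sample(
    plan: IterationPlan,
    iteration_id: int,
    table: pd.DataFrame,
    subsample_sets: dict,
    n_presence: int,
    n_absence: int,
    seed: int,
    response: str = "road_present",
) -> TreeDraw:
    """Balanced bootstrap draw for one tree.

    Draws exactly ``n_presence`` presences and ``n_absence`` absences with
    replacement from the union of the iteration's per-region subsamples.
    Zero class counts are rejected, as is a pool missing either class.
    """
    if n_presence < 1 or n_absence < 1:
        raise ValueError("per-tree class counts must be >= 1")
    pres, absn = iteration_pool(plan, iteration_id, subsample_sets, table, response)
    if len(pres) == 0 or len(absn) == 0:
        raise ValueError(
            f"iteration {iteration_id} pool lacks a class: "
            f"{len(pres)} presences, {len(absn)} absences"
        )
    rng = np.random.default_rng(seed)
    drawn = np.concatenate(
        [
            rng.choice(pres, size=n_presence, replace=True),
            rng.choice(absn, size=n_absence, replace=True),
        ]
    )
    return TreeDraw(
        iteration_id=iteration_id,
        indices=drawn,
        n_presence=n_presence,
        n_absence=n_absence,
        seed=seed,
    )


def draw_prevalence_sample(
    table: pd.DataFrame,
    n_per_region: int,
    seed: int,
    response: str = "road_present",
    exclude: np.ndarray | None = None,
    regions: list | None = None,
    max_retries: int = 5,
) -> np.ndarray:
    """Stratified evaluation draw at each region's original prevalence.

    Draws ``n_per_region`` records per region, with the presence count
    set to round(prevalence * n_per_region), so evaluation sees the
    landscape's own class balance rather than the training sample's.
    ``exclude`` removes indices (e.g. training subsamples) from the pool.
    If a draw would be single-class it is retried with a fresh sub-seed a
    bounded number of times, then errors.
    """
    if regions is None:
        regions = sorted(table["region"].unique())
    pool_table = table
    if exclude is not None and len(exclude):
        pool_table = table.drop(index=np.unique(exclude))
    parts = []
    for region in regions:
        sub = pool_table[pool_table["region"] == region]
        if len(sub) == 0:
            raise ValueError(f"region {region!r} has no records to evaluate on")
        y = sub[response].to_numpy()
        pres = sub.index.to_numpy()[y == 1]
        absn = sub.index.to_numpy()[y == 0]
        prevalence = len(pres) / len(sub)
        for attempt in range(max_retries):
            rng = np.random.default_rng(derive_seed(seed, "eval", region, attempt))
            n_p = int(round(prevalence * n_per_region))
            n_p = min(max(n_p, 0), n_per_region)
            n_a = n_per_region - n_p
            if 0 < n_p and 0 < n_a and len(pres) and len(absn):
                parts.append(rng.choice(pres, size=n_p, replace=len(pres) < n_p))
                parts.append(rng.choice(absn, size=n_a, replace=len(absn) < n_a))
                break
        else:
            raise ValueError(
                f"could not draw a two-class evaluation sample for region {region!r} "
                f"(prevalence {prevalence:.4f}, n={n_per_region})"
            )
    return np.concatenate(parts)
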