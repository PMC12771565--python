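"""Rank encoding of categorical covariates.

Tree-based routines that subsample and recombine trees cannot carry
categorical levels across samples, so categorical covariates (country,
administrative region, vegetation class, protected-area class, ...) are
converted to numeric ranks: classes are ordered by their mean response
(road or impact presence) and replaced by consecutive integer ranks,
1 = lowest mean.  Compared to target encoding this leaks less response
information because only the ordering survives, not the means.

A per-country grouping variant ranks each (country, class) combination in
one pooled ordering, so e.g. private protected areas may rank differently
in different countries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = ["RankEncoding", "fit_rank_encoding", "apply_rank_encoding"]

_NOGROUP = "__all__"


@dataclass
class RankEncoding:
    """Fitted rank encoding for one categorical variable.

    ``mapping`` sends a (group, class) key to an integer rank in 1..K
    (K = number of keys seen); ``class_means`` holds the response means
    the ranking was derived from.  With ``grouping == "none"`` the group
    component is a fixed sentinel.
    """

    variable: str = ""
    grouping: str = "none"  # "none" | "country"
    mapping: dict = field(default_factory=dict)
    class_means: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.mapping)

    def to_dict(self) -> dict:
        """JSON/YAML-serializable form (keys flattened to strings)."""
        return {
            "variable": self.variable,
            "grouping": self.grouping,
            "mapping": {f"{g}␟{c}": r for (g, c), r in self.mapping.items()},
            "class_means": {
                f"{g}␟{c}": m for (g, c), m in self.class_means.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RankEncoding":
        def unflat(k: str) -> tuple:
            g, c = k.split("␟", 1)
            return (g, c)

        return cls(
            variable=d["variable"],
            grouping=d["grouping"],
            mapping={unflat(k): int(v) for k, v in d["mapping"].items()},
            class_means={unflat(k): float(v) for k, v in d["class_means"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RankEncoding":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _keys(classes: Sequence, groups: Sequence | None) -> list[tuple]:
    if groups is None:
        return [(_NOGROUP, str(c)) for c in classes]
    return [(str(g), str(c)) for g, c in zip(groups, classes)]


def fit_rank_encoding(
    classes: Sequence[Hashable],
    responses: Sequence[int],
    groups: Sequence[Hashable] | None = None,
    variable: str = "",
) -> RankEncoding:
    """Rank classes by mean binary response.

    Rank 1 is the lowest class mean, rank K the highest.  Ties in the
    mean are broken lexicographically by class label (then group), so the
    fit is deterministic and seed-free.  When ``groups`` is given, every
    (group, class) combination is ranked in a single pooled ordering.
    """
    classes = list(classes)
    responses = np.asarray(list(responses))
    if len(classes) == 0:
        raise ValueError("cannot fit a rank encoding on empty input")
    if len(classes) != len(responses):
        raise ValueError("classes and responses must have equal length")
    if not np.isin(responses, [0, 1]).all():
        raise ValueError("responses must be binary 0/1")
    if groups is not None and len(groups) != len(classes):
        raise ValueError("groups must match classes in length")

    keys = _keys(classes, groups)
    sums: dict[tuple, float] = {}
    counts: dict[tuple, int] = {}
    for k, y in zip(keys, responses):
        sums[k] = sums.get(k, 0.0) + float(y)
        counts[k] = counts.get(k, 0) + 1
    means = {k: sums[k] / counts[k] for k in sums}

    # sort by (mean, class label, group): lexicographic tie-break on label
    ordered = sorted(means, key=lambda k: (means[k], k[1], k[0]))
    mapping = {k: rank for rank, k in enumerate(ordered, start=1)}
    return RankEncoding(
        variable=variable,
        grouping="none" if groups is None else "country",
        mapping=mapping,
        class_means=means,
    )


def apply_rank_encoding(
    enc: RankEncoding,
    classes: Sequence[Hashable],
    groups: Sequence[Hashable] | None = None,
    unseen: str = "error",
) -> np.ndarray:
    """Replace class labels by their fitted ranks.

    ``unseen`` policy for (group, class) keys not in the fit:
    ``"error"`` (default) raises; ``"median"`` maps to the median of the
    rank range 1..K.
    """
    if enc.grouping == "country" and groups is None:
        raise ValueError("encoding was fitted with grouping; groups required")
    if enc.grouping == "none" and groups is not None:
        raise ValueError("encoding was fitted without grouping")
    if unseen not in ("error", "median"):
        raise ValueError(f"unknown unseen-class policy {unseen!r}")
    keys = _keys(list(classes), groups)
    k_total = enc.n_classes
    median_rank = (1 + k_total) / 2.0
    out = np.empty(len(keys), dtype=float)
    for i, key in enumerate(keys):
        rank = enc.mapping.get(key)
        if rank is None:
            if unseen == "error":
                raise KeyError(
                    f"unseen class {key[1]!r} (group {key[0]!r}) for variable "
                    f"{enc.variable!r}; enable unseen='median' to map to the median rank"
                )
            out[i] = median_rank
        else:
            out[i] = rank
    return out
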