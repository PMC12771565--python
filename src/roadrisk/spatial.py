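"""Spatial and ranking primitives: residuals autocovariate, Moran's I,
focal means, and AUC.

These are the numeric workhorses behind the modelling routine.  All grid
operations treat the landscape as a planar row/column raster of 1-ha
cells; neighbourhood weights are binary, the focal cell is excluded for
autocovariate and Moran computations, and edges shrink to the available
cells (no wraparound, no padding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

__all__ = [
    "NeighborhoodSpec",
    "neighborhood_kernel",
    "residual_autocovariate",
    "morans_i",
    "focal_mean",
    "auc",
]


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Binary-weight neighbourhood on the cell grid.

    scheme
        ``rook``  — Manhattan distance <= radius,
        ``queen`` — Chebyshev distance <= radius,
        ``radius`` — Euclidean distance <= radius.
    radius
        In cell units, >= 1.
    include_focal
        Fixed False: the focal cell never neighbours itself.
    """

    scheme: str = "queen"
    radius: int = 1
    include_focal: bool = False

    def __post_init__(self) -> None:
        if self.scheme not in ("rook", "queen", "radius"):
            raise ValueError(f"unknown neighbourhood scheme {self.scheme!r}")
        if self.radius < 1:
            raise ValueError("neighbourhood radius must be >= 1")
        if self.include_focal:
            raise ValueError("include_focal is fixed False for neighbourhoods")


def neighborhood_kernel(nbh: NeighborhoodSpec) -> np.ndarray:
    """Binary (0/1) convolution kernel for a neighbourhood spec."""
    r = nbh.radius
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    if nbh.scheme == "rook":
        mask = (np.abs(dr) + np.abs(dc)) <= r
    elif nbh.scheme == "queen":
        mask = np.maximum(np.abs(dr), np.abs(dc)) <= r
    else:
        mask = (dr**2 + dc**2) <= r**2
    mask[r, r] = False
    return mask.astype(float)


def _neighbor_sums(grid: np.ndarray, kernel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell neighbour value sums and in-grid neighbour counts."""
    sums = ndimage.convolve(grid, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(grid), kernel, mode="constant", cval=0.0)
    return sums, counts


def residual_autocovariate(
    grid: np.ndarray, nbh: NeighborhoodSpec = NeighborhoodSpec()
) -> np.ndarray:
    """Residuals autocovariate (RAC / SAR term): per-cell mean of the
    neighbouring cells' residuals, focal cell excluded.

    Cells whose neighbourhood falls entirely off-grid get 0 and are
    counted in a warning.  Linear in the residual grid by construction.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty residual grid")
    kernel = neighborhood_kernel(nbh)
    sums, counts = _neighbor_sums(grid, kernel)
    isolated = counts == 0
    n_isolated = int(isolated.sum())
    if n_isolated:
        warnings.warn(
            f"{n_isolated} cells have no in-grid neighbours; their autocovariate is 0",
            stacklevel=2,
        )
    out = np.zeros_like(grid)
    np.divide(sums, counts, out=out, where=~isolated)
    return out


def morans_i(values: np.ndarray, nbh: NeighborhoodSpec = NeighborhoodSpec()) -> float:
    """Global Moran's I with binary adjacency weights on the grid.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    Weights are not row-standardised.  Under independence the expectation
    is -1/(n-1); a rook-weight checkerboard attains -1.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("Moran's I needs at least 2 cells")
    z = values - values.mean()
    denom = float((z**2).sum())
    if denom == 0.0:
        raise ValueError("Moran's I undefined for zero-variance values")
    kernel = neighborhood_kernel(nbh)
    lagged, counts = _neighbor_sums(z, kernel)
    num = float((z * lagged).sum())
    w_total = float(counts.sum())
    return (n / w_total) * num / denom


def focal_mean(grid: np.ndarray, radius: int) -> np.ndarray:
    """Circular focal mean: average over all in-grid cells within
    Euclidean distance ``radius`` of the focal cell, focal included.

    Edge cells average over the cells actually available.
    """
    if radius < 1:
        raise ValueError("focal radius must be >= 1")
    grid = np.asarray(grid, dtype=float)
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    kernel = ((dr**2 + dc**2) <= radius**2).astype(float)
    sums, counts = _neighbor_sums(grid, kernel)
    return sums / counts


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals P(score+ > score-) + 0.5 * P(tie) over presence/absence
    pairs.  Raises if only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    rank_sum = float(ranks[pos].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
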