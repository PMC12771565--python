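"""Independent brute-force oracles for the spatial/ranking primitives.

Everything here is deliberately naive — O(n^2) double loops and
exhaustive pair counting — and shares no code with the package
implementations it checks.
"""

import numpy as np


def neighbor_offsets(scheme: str, radius: int):
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            if scheme == "rook" and abs(dr) + abs(dc) > radius:
                continue
            if scheme == "queen" and max(abs(dr), abs(dc)) > radius:
                continue
            if scheme == "radius" and dr**2 + dc**2 > radius**2:
                continue
            out.append((dr, dc))
    return out


def brute_force_autocovariate(grid, scheme="queen", radius=1):
    rows, cols = grid.shape
    offsets = neighbor_offsets(scheme, radius)
    out = np.zeros_like(grid, dtype=float)
    for i in range(rows):
        for j in range(cols):
            vals = [
                grid[i + dr, j + dc]
                for dr, dc in offsets
                if 0 <= i + dr < rows and 0 <= j + dc < cols
            ]
            out[i, j] = np.mean(vals) if vals else 0.0
    return out


def brute_force_morans(grid, scheme="queen", radius=1):
    rows, cols = grid.shape
    offsets = neighbor_offsets(scheme, radius)
    z = grid - grid.mean()
    num = 0.0
    w_total = 0
    for i in range(rows):
        for j in range(cols):
            for dr, dc in offsets:
                if 0 <= i + dr < rows and 0 <= j + dc < cols:
                    num += z[i, j] * z[i + dr, j + dc]
                    w_total += 1
    n = grid.size
    return (n / w_total) * num / (z**2).sum()


def morans_null_sd(shape, scheme="rook", radius=1):
    """Normal-approximation sd of Moran's I under independence.

    Var_N(I) = (n^2 S1 - n S2 + 3 W^2) / (W^2 (n^2 - 1)) - E[I]^2 with
    S1 = 2W and S2 = 4 * sum_i rowsum_i^2 for binary symmetric weights.
    """
    rows, cols = shape
    offsets = neighbor_offsets(scheme, radius)
    rowsums = np.zeros(shape)
    for i in range(rows):
        for j in range(cols):
            rowsums[i, j] = sum(
                1
                for dr, dc in offsets
                if 0 <= i + dr < rows and 0 <= j + dc < cols
            )
    n = rows * cols
    W = rowsums.sum()
    s1 = 2 * W
    s2 = 4 * (rowsums**2).sum()
    e_i = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * W**2) / (W**2 * (n**2 - 1)) - e_i**2
    return float(np.sqrt(var))


def brute_force_focal_mean(grid, radius):
    rows, cols = grid.shape
    out = np.empty_like(grid, dtype=float)
    for i in range(rows):
        for j in range(cols):
            vals = []
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr**2 + dc**2 > radius**2:
                        continue
                    if 0 <= i + dr < rows and 0 <= j + dc < cols:
                        vals.append(grid[i + dr, j + dc])
            out[i, j] = np.mean(vals)
    return out


def brute_force_auc(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_best_threshold(labels, scores):
    """Exhaustive scan over observed scores for max sensitivity+specificity."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    best_t, best_obj = None, -np.inf
    for t in sorted(set(scores.tolist())):
        pred = scores >= t
        sens = pred[labels == 1].mean()
        spec = (~pred[labels == 0]).mean()
        if sens + spec > best_obj:
            best_obj, best_t = sens + spec, t
    return best_t
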