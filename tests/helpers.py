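"""Independent oracles used by the unit and acceptance tests.

These deliberately recompute results by brute force (exhaustive enumeration,
dense sampling, naive O(n^3) agglomeration) so they share no code path with
the implementation they check.
"""

from __future__ import annotations

import numpy as np


def brute_hex_assign(x: float, y: float, grid) -> str:
    """Exhaustive nearest-center search over ALL lattice centers in range.

    Enumerates every center of both sublattices within (and one ring beyond)
    the grid ranges, compares exact scaled Euclidean distances, and breaks
    ties toward the lexicographically smallest (center_x, center_y).
    """
    w, h = grid.hex_width, grid.hex_height
    x0, y0 = grid.x_range[0], grid.y_range[0]
    u = (x - x0) / w
    v = (y - y0) / h
    span_u = (grid.x_range[1] - x0) / w
    span_v = (grid.y_range[1] - y0) / h
    best = None
    for qi in range(-2, 2 * int(np.ceil(span_u)) + 3):
        for qj in range(-2, 2 * int(np.ceil(span_v)) + 3):
            if (qi % 2) != (qj % 2):
                continue  # centers exist only where parities agree
            cu, cv = qi / 2.0, qj / 2.0
            d = (u - cu) ** 2 + (v - cv) ** 2
            key = (d, cu, cv)
            if best is None or key < best[0]:
                best = (key, f"{qi}:{qj}")
    return best[1]


def dense_box_oracle(values: np.ndarray, query, n_per_unit: int = 1000) -> np.ndarray:
    """Dense-sampling evaluation of the continuous box-selection predicate.

    Samples each polyline at ``n_per_unit`` points per unit x across the
    clipped query interval (plus the contained axis vertices and the interval
    endpoints, so piecewise-linear extrema are hit exactly), via np.interp.
    Returns a boolean retention mask; a query missing all axes retains all.
    """
    n_genes, n_axes = values.shape
    pos = np.arange(1, n_axes + 1, dtype=float)
    a, b = max(query.x1, 1.0), min(query.x2, float(n_axes))
    if a > b:
        return np.ones(n_genes, dtype=bool)
    n_samples = max(2, int(np.ceil((b - a) * n_per_unit)) + 1)
    xs = np.linspace(a, b, n_samples)
    vertices = pos[(pos >= a) & (pos <= b)]
    xs = np.union1d(xs, vertices)
    keep = np.empty(n_genes, dtype=bool)
    for g in range(n_genes):
        f = np.interp(xs, pos, values[g])
        keep[g] = bool(((f >= query.y1) & (f <= query.y2)).all())
    return keep


def naive_linkage(data: np.ndarray, method: str):
    """O(n^3) agglomeration recomputing inter-cluster distances from raw points.

    Supports single / complete / average, whose inter-cluster distance has a
    direct definition (min / max / mean over all cross pairs).  Cluster ids
    mirror hclust bookkeeping: leaves 0..n-1, merge i creates id n+i; ties
    break toward the lexicographically smallest (older id, newer id) pair.
    Returns (merges, heights) with merges as (id_a, id_b) tuples.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    pair_d = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges, heights = [], []
    for step in range(n - 1):
        ids = sorted(clusters)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                cross = pair_d[np.ix_(clusters[a], clusters[b])]
                if method == "single":
                    d = cross.min()
                elif method == "complete":
                    d = cross.max()
                elif method == "average":
                    d = cross.mean()
                else:
                    raise ValueError(method)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        new_id = n + step
        clusters[new_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b))
        heights.append(float(d))
    return merges, heights


def naive_cut(merges, n: int, k: int) -> list[frozenset[int]]:
    """Partition of leaves after undoing the last k-1 merges (components)."""
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b = merges[step]
        new_id = n + step
        parent[find(a)] = new_id
        parent[find(b)] = new_id
    groups: dict[int, set[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), set()).add(leaf)
    return [frozenset(g) for g in groups.values()]


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjustment (the FDR oracle)."""
    pvals = np.asarray(pvals, dtype=float)
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * n / rank)
        adjusted[idx] = running
    return adjusted
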