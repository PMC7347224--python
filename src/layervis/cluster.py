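"""Agglomerative hierarchical clustering of gene profiles.

Implements the classic hclust/cutree semantics over Euclidean distances
between standardized profiles, with the full agglomeration menu — ward.D,
ward.D2, single, complete, average, mcquitty (WPGMA), median (WPGMC),
centroid (UPGMC) — via the Lance–Williams recurrence.  ward.D applies the
Ward update to the supplied distances as given; ward.D2, median and centroid
update squared distances and report square-rooted merge heights.  Ties among
equal-distance merges break toward the lexicographically smallest
(older cluster id, newer cluster id) pair, so trees are deterministic.

Cluster overlays follow three approaches: (1) cluster only a user subset and
overlay it; (2) cluster the full dataset, overlay only the subset colored by
its full-data clusters; (3) cluster the full dataset and overlay everything.
Every cluster's parallel-coordinate figure keeps the five-number-summary
underlay of the FULL dataset, and cluster colors come from one fixed palette
shared by all plot builders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import ExpressionMatrix, GeneList
from .engine import LayeredFigure, LayerSession
from .errors import ValidationError
from .pcp import ProfileSet, build_pcp, profiles_from_matrix

__all__ = [
    "METHODS",
    "DEFAULT_METHOD",
    "CLUSTER_PALETTE",
    "LinkageTree",
    "ClusterAssignment",
    "linkage",
    "cut",
    "cluster_overlay",
    "save_cluster_ids",
]

METHODS = (
    "ward.D",
    "ward.D2",
    "single",
    "complete",
    "average",
    "mcquitty",
    "median",
    "centroid",
)
DEFAULT_METHOD = "ward.D"

#: Methods whose Lance-Williams update runs on squared Euclidean distances,
#: with merge heights reported on the original scale.
_SQUARED = ("ward.D2", "median", "centroid")

#: Fixed ordered palette so cluster k is the same color in every plot type.
CLUSTER_PALETTE = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
)


@dataclass(frozen=True)
class LinkageTree:
    """Merge history: (cluster_a, cluster_b, height) triples over cluster ids.

    Leaves are ids 0..n−1 in leaf order; merge i creates cluster n+i.
    """

    merges: tuple[tuple[int, int, float], ...]
    method: str
    leaf_ids: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> tuple[float, ...]:
        return tuple(h for _, _, h in self.merges)


@dataclass(frozen=True)
class ClusterAssignment:
    """gene id → cluster index in 1..k, plus the stable color palette."""

    assignment: Mapping[str, int]
    k: int
    method: str
    approach: int | None = None
    palette: Mapping[int, str] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cluster]

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for g, c in self.assignment.items():
            out[c].append(g)
        return out


def _lw_update(
    method: str, d_ac: np.ndarray, d_bc: np.ndarray, d_ab: float,
    na: int, nb: int, nc: np.ndarray,
) -> np.ndarray:
    """Distance from the merged cluster (a∪b) to every other cluster c."""
    if method == "single":
        return np.minimum(d_ac, d_bc)
    if method == "complete":
        return np.maximum(d_ac, d_bc)
    if method == "average":
        return (na * d_ac + nb * d_bc) / (na + nb)
    if method == "mcquitty":
        return 0.5 * d_ac + 0.5 * d_bc
    if method == "median":
        return 0.5 * d_ac + 0.5 * d_bc - 0.25 * d_ab
    if method == "centroid":
        s = na + nb
        return (na * d_ac + nb * d_bc) / s - (na * nb * d_ab) / (s * s)
    if method in ("ward.D", "ward.D2"):
        s = na + nb + nc
        return ((na + nc) * d_ac + (nb + nc) * d_bc - nc * d_ab) / s
    raise ValidationError(f"unknown method {method!r}")


def linkage(profiles: ProfileSet | np.ndarray, method: str = DEFAULT_METHOD) -> LinkageTree:
    """Agglomerate Euclidean distances between profiles with the named method.

    Accepts a :class:`ProfileSet` (typically standardized) or a raw
    (n_items × n_features) array; leaves keep input order.
    """
    if method not in METHODS:
        raise ValidationError(
            f"unknown agglomeration method {method!r}; choose one of {list(METHODS)}"
        )
    if isinstance(profiles, ProfileSet):
        data = np.asarray(profiles.values, dtype=float)
        leaf_ids = profiles.gene_ids
    else:
        data = np.asarray(profiles, dtype=float)
        leaf_ids = tuple(str(i) for i in range(data.shape[0]))
    n = data.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 profiles to cluster, got {n}")

    d = squareform(pdist(data, metric="euclidean"))
    if method in _SQUARED:
        d = d**2
    big = np.inf
    np.fill_diagonal(d, big)

    ids = list(range(n))  # active cluster ids, ascending
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    # rows/cols of `d` track `ids` positionally
    for step in range(n - 1):
        # smallest distance; among ties the first in row-major upper-triangle
        # order, i.e. the lexicographically smallest (older id, newer id)
        iu = np.triu_indices(len(ids), k=1)
        flat = d[iu]
        best = int(np.argmin(flat))
        pi, pj = int(iu[0][best]), int(iu[1][best])
        a, b = ids[pi], ids[pj]
        height = float(flat[best])
        new_id = n + step
        na, nb = sizes[a], sizes[b]

        keep = [p for p in range(len(ids)) if p not in (pi, pj)]
        nc = np.array([sizes[ids[p]] for p in keep], dtype=float)
        d_ac = d[pi, keep]
        d_bc = d[pj, keep]
        d_new = _lw_update(method, d_ac, d_bc, height, na, nb, nc)

        merges.append(
            (a, b, float(np.sqrt(height)) if method in _SQUARED else height)
        )
        # rebuild the reduced matrix with the new cluster appended last
        m = len(keep)
        nd = np.full((m + 1, m + 1), big)
        nd[:m, :m] = d[np.ix_(keep, keep)]
        nd[:m, m] = d_new
        nd[m, :m] = d_new
        d = nd
        ids = [ids[p] for p in keep] + [new_id]
        sizes[new_id] = na + nb
    return LinkageTree(tuple(merges), method, tuple(leaf_ids))


def cut(tree: LinkageTree, k: int) -> ClusterAssignment:
    """Undo the last k−1 merges: exactly k non-empty clusters, indexed by
    order of first appearance among the leaves (cutree semantics)."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        a, b, _ = tree.merges[step]
        new_id = n + step
        parent[find(a)] = new_id
        parent[find(b)] = new_id
    labels: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for leaf, gene in enumerate(tree.leaf_ids):
        root = find(leaf)
        if root not in labels:
            labels[root] = len(labels) + 1
        assignment[gene] = labels[root]
    palette = {
        c: CLUSTER_PALETTE[(c - 1) % len(CLUSTER_PALETTE)] for c in range(1, k + 1)
    }
    return ClusterAssignment(assignment, k, tree.method, palette=palette)


def cluster_overlay(
    matrix: ExpressionMatrix,
    subset: GeneList | None,
    k: int,
    method: str = DEFAULT_METHOD,
    approach: int = 1,
    standardized: bool = True,
    session: LayerSession | None = None,
) -> tuple[ClusterAssignment, dict[int, LayeredFigure]]:
    """Cluster profiles and build one parallel-coordinate figure per cluster.

    Approach 1 clusters only ``subset`` and overlays it; approach 2 clusters
    the full dataset and overlays only ``subset``, colored by full-data
    cluster; approach 3 clusters and overlays everything.  All figures keep
    the full dataset's five-number-summary underlay.
    """
    if approach not in (1, 2, 3):
        raise ValidationError(f"approach must be 1, 2 or 3, got {approach}")
    if approach in (1, 2) and (subset is None or len(subset) == 0):
        raise ValidationError(f"approach {approach} requires a non-empty gene subset")
    full = profiles_from_matrix(matrix, standardized=standardized)
    if subset is not None:
        subset.resolve(matrix)

    if approach == 1:
        clustered = full.subset(list(subset))
    else:
        clustered = full
    tree = linkage(clustered, method)
    assignment = cut(tree, k)

    if approach == 2:
        overlay_ids = tuple(subset)
    elif approach == 1:
        overlay_ids = tuple(subset)
    else:
        overlay_ids = full.gene_ids
    assignment = ClusterAssignment(
        assignment.assignment, k, method, approach, assignment.palette
    )

    session = session or LayerSession()
    figures: dict[int, LayeredFigure] = {}
    for c in range(1, k + 1):
        members = [g for g in overlay_ids if assignment.assignment.get(g) == c]
        figures[c] = build_pcp(
            full,
            overlay=GeneList.of(members),
            show_summary=True,
            color=assignment.palette[c],
            session=session,
        )
    return assignment, figures


def save_cluster_ids(
    assignment: ClusterAssignment, directory: str | Path
) -> list[Path]:
    """One plain-text file per cluster (one gene id per line), deterministic names."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for c, members in sorted(assignment.clusters().items()):
            path = directory / f"cluster_{c}_of_{assignment.k}_{assignment.method}.txt"
            path.write_text("".join(f"{g}\n" for g in members))
            paths.append(path)
    except OSError as exc:
        raise OSError(f"cannot write cluster ids under {directory}: {exc}") from exc
    return paths
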