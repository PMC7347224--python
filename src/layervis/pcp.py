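"""Parallel-coordinate profiles, five-number summaries, and consecutive box
selection.

A :class:`ProfileSet` places samples at integer x-positions 1..n (first
treatment's replicates, then the second's, in design order) and draws each
gene as the piecewise-linear polyline through (axis position, value).  The
box-selection predicate is *continuous*: a gene survives a query rectangle
[x1, x2] × [y1, y2] iff its polyline satisfies y1 ≤ f(x) ≤ y2 for **every**
x in [x1, x2] ∩ [1, n] — not just at the axis vertices.  Because f is
piecewise linear, its extrema on an interval occur at contained axis vertices
or at the interval endpoints, so the predicate is evaluated exactly from
those finitely many values (the vertex-and-endpoint criterion).  Consecutive
queries intersect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import engine
from .core import ExpressionMatrix, GeneList
from .engine import ForegroundLayer, LayerSession, LayeredFigure
from .errors import ValidationError

__all__ = [
    "ProfileSet",
    "BoxQuery",
    "FiveNumberSummary",
    "standardize",
    "profiles_from_matrix",
    "five_number_summary",
    "box_select",
    "consecutive_select",
    "build_pcp",
]


@dataclass(frozen=True)
class BoxQuery:
    """Axis-aligned query rectangle with x2 ≥ x1 and y2 ≥ y1."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self) -> None:
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValidationError(
                f"malformed box query: need x2 >= x1 and y2 >= y1, got "
                f"({self.x1}, {self.y1})-({self.x2}, {self.y2})"
            )


@dataclass(frozen=True)
class FiveNumberSummary:
    """Per-axis (min, Q1, median, Q3, max); rows follow the axis order."""

    axes: tuple[str, ...]
    values: np.ndarray  # shape (n_axes, 5)

    def for_axis(self, label: str) -> tuple[float, float, float, float, float]:
        idx = self.axes.index(label)
        return tuple(float(v) for v in self.values[idx])


@dataclass(frozen=True)
class ProfileSet:
    """Gene profiles over ordered sample axes at x-positions 1..n."""

    axes: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_axes)
    standardized: bool = False
    constant_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.gene_ids), len(self.axes)):
            raise ValidationError(
                f"profile values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.axes)} axes"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("profiles contain non-finite values")

    @property
    def n_axes(self) -> int:
        return len(self.axes)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_axes + 1, dtype=float)

    def subset(self, genes: Sequence[str]) -> "ProfileSet":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"profiles missing genes: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ProfileSet(
            self.axes,
            tuple(genes),
            self.values[rows],
            self.standardized,
            self.constant_genes & set(genes),
        )


def standardize(matrix: ExpressionMatrix) -> ProfileSet:
    """Per-gene standardization: (value − row mean) / row sd, sd with n−1.

    Constant rows (sd = 0) map to all-zeros and are flagged in
    ``constant_genes`` so callers can annotate rather than divide by zero.
    """
    counts = np.asarray(matrix.counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValidationError("standardization needs at least 2 samples")
    mean = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (counts - mean) / safe_sd
    z[constant] = 0.0
    return ProfileSet(
        tuple(matrix.sample_labels),
        tuple(matrix.gene_ids),
        z,
        standardized=True,
        constant_genes=frozenset(np.asarray(matrix.gene_ids)[constant]),
    )


def profiles_from_matrix(matrix: ExpressionMatrix, standardized: bool = True) -> ProfileSet:
    """Profiles over all samples, standardized by default (raw counts otherwise)."""
    if standardized:
        return standardize(matrix)
    return ProfileSet(
        tuple(matrix.sample_labels),
        tuple(matrix.gene_ids),
        np.asarray(matrix.counts, dtype=float).copy(),
    )


def five_number_summary(profiles: ProfileSet) -> FiveNumberSummary:
    """Per-axis min/Q1/median/Q3/max; quartiles by linear interpolation of
    order statistics (position 1 + p·(n−1))."""
    if len(profiles.gene_ids) == 0:
        raise ValidationError("five-number summary of an empty profile set")
    qs = np.quantile(
        profiles.values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0, method="linear"
    )
    return FiveNumberSummary(profiles.axes, qs.T.copy())


def _interp_at(profiles: ProfileSet, x: float) -> np.ndarray:
    """f(x) for every gene's polyline; x must lie within [1, n]."""
    pos = profiles.positions
    lo = int(np.clip(np.floor(x), 1, profiles.n_axes)) - 1
    hi = min(lo + 1, profiles.n_axes - 1)
    if pos[lo] == x or lo == hi:
        return profiles.values[:, lo]
    t = (x - pos[lo]) / (pos[hi] - pos[lo])
    return (1.0 - t) * profiles.values[:, lo] + t * profiles.values[:, hi]


def box_select(profiles: ProfileSet, query: BoxQuery) -> GeneList:
    """Genes whose polyline stays inside [y1, y2] over all of [x1, x2] ∩ [1, n].

    Evaluated exactly via the vertex-and-endpoint criterion.  A query whose
    x-range misses every axis retains all genes (the universal quantifier is
    vacuous); this is logged as a warning since it is usually a mis-drawn box.
    """
    a = max(query.x1, 1.0)
    b = min(query.x2, float(profiles.n_axes))
    if a > b:
        warnings.warn(
            f"box query x-range [{query.x1}, {query.x2}] misses all axes; "
            "all genes retained",
            stacklevel=2,
        )
        return GeneList.of(profiles.gene_ids)
    checks = [_interp_at(profiles, a)]
    first_axis = int(np.ceil(a))
    last_axis = int(np.floor(b))
    for k in range(first_axis, last_axis + 1):
        checks.append(profiles.values[:, k - 1])
    if b != a:
        checks.append(_interp_at(profiles, b))
    stacked = np.stack(checks, axis=1)
    ok = ((stacked >= query.y1) & (stacked <= query.y2)).all(axis=1)
    return GeneList.of(np.asarray(profiles.gene_ids)[ok])


def consecutive_select(
    profiles: ProfileSet, queries: Sequence[BoxQuery]
) -> GeneList:
    """Genes retained by every query: the intersection of single-query results,
    in profile order.  An empty query list retains everything."""
    keep = set(profiles.gene_ids)
    for query in queries:
        keep &= set(box_select(profiles, query))
    return GeneList.of([g for g in profiles.gene_ids if g in keep])


def build_pcp(
    profiles: ProfileSet,
    overlay: GeneList | None = None,
    show_summary: bool = True,
    alpha: float = 0.6,
    color: str = engine.PINK,
    session: LayerSession | None = None,
) -> LayeredFigure:
    """Parallel-coordinate figure: five-number-summary boxes as the background
    (when shown), overlay polylines with hover gene names as the foreground."""
    session = session or LayerSession()
    axes_meta = {
        "x": list(profiles.axes),
        "positions": profiles.positions.tolist(),
        "standardized": profiles.standardized,
    }
    if show_summary:
        summary = five_number_summary(profiles)
        doc = {
            "boxes": [
                {
                    "axis": label,
                    "position": float(profiles.positions[i]),
                    "min": float(summary.values[i, 0]),
                    "q1": float(summary.values[i, 1]),
                    "median": float(summary.values[i, 2]),
                    "q3": float(summary.values[i, 3]),
                    "max": float(summary.values[i, 4]),
                }
                for i, label in enumerate(profiles.axes)
            ]
        }
        hover = {
            label: (
                f"{label}: min {doc['boxes'][i]['min']:g}, "
                f"Q1 {doc['boxes'][i]['q1']:g}, median {doc['boxes'][i]['median']:g}, "
                f"Q3 {doc['boxes'][i]['q3']:g}, max {doc['boxes'][i]['max']:g}"
            )
            for i, label in enumerate(profiles.axes)
        }
        fig = engine.summary_background(
            doc,
            hover,
            cache_key_seed=doc,
            session=session,
            axes=axes_meta,
            known_ids=profiles.gene_ids,
            meta={"plot": "pcp"},
        )
    else:
        fig = engine.summary_background(
            {"boxes": []},
            {},
            cache_key_seed={"empty": list(profiles.axes)},
            session=session,
            axes=axes_meta,
            known_ids=profiles.gene_ids,
            meta={"plot": "pcp"},
        )
    if overlay is None or len(overlay) == 0:
        return fig
    sub = profiles.subset(list(overlay))
    paths = [
        (g, list(zip(profiles.positions.tolist(), sub.values[i].tolist())))
        for i, g in enumerate(sub.gene_ids)
    ]
    return engine.update_foreground(
        fig, ForegroundLayer.polylines(paths, alpha=alpha, color=color)
    )
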