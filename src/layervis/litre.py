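"""Litre (repLIcate TREatment) plots.

The scatterplot matrix collapsed onto one Cartesian plane for a treatment
pair: for every gene g and every between-treatment replicate combination
(replicate i of the first treatment, replicate j of the second), one
background point (count(g, first.i), count(g, second.j)).  A matrix of G
genes with m and n replicates therefore yields G·m·n background points,
hexbinned once; one gene's m·n combination points are overlaid at a time,
stepped through in metric order (FDR ascending, typically).

Axis orientation: pair.first on x, pair.second on y.  Only between-treatment
combinations are plotted — the plot's purpose is treatment-vs-treatment
variability, so within-treatment pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import engine
from .core import ExpressionMatrix, MetricsTable, TreatmentPair
from .engine import ForegroundLayer, LayerSession, LayeredFigure
from .errors import IteratorExhausted, UnknownIdError, ValidationError

__all__ = [
    "GeneIterator",
    "build_litre_background",
    "litre_points_for_gene",
    "order_genes",
    "plot_next_gene",
]


@dataclass(frozen=True)
class GeneIterator:
    """A metric-ordered tour over genes with a cursor (0 = nothing plotted yet)."""

    gene_ids: tuple[str, ...]
    metric: str
    order: str
    cursor: int = 0

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def exhausted(self) -> bool:
        return self.cursor >= len(self.gene_ids)

    @property
    def current(self) -> str:
        if self.exhausted:
            raise IteratorExhausted(
                f"all {len(self.gene_ids)} genes have been plotted"
            )
        return self.gene_ids[self.cursor]


def _combination_points(
    matrix: ExpressionMatrix, pair: TreatmentPair, gene_rows: Sequence[int]
) -> list[tuple[str, float, float]]:
    design = matrix.design
    cols_first = design.columns_for(pair.first)
    cols_second = design.columns_for(pair.second)
    reps_first = design.replicates_of[pair.first]
    reps_second = design.replicates_of[pair.second]
    counts = np.asarray(matrix.counts)
    points = []
    for row in gene_rows:
        gene = matrix.gene_ids[row]
        for ci, ri in zip(cols_first, reps_first):
            for cj, rj in zip(cols_second, reps_second):
                pid = f"{gene}#{pair.first}.{ri}|{pair.second}.{rj}"
                points.append((pid, float(counts[row, ci]), float(counts[row, cj])))
    return points


def build_litre_background(
    matrix: ExpressionMatrix,
    pair: TreatmentPair,
    n_bins: int = 10,
    session: LayerSession | None = None,
) -> LayeredFigure:
    """Hexbin the G·m·n cross-combination point cloud (the time-limiting step)."""
    points = _combination_points(matrix, pair, range(matrix.n_genes))
    fig = engine.build_background(
        points,
        geom="hexagon",
        n_bins=n_bins,
        session=session or LayerSession(),
        axes={"x": pair.first, "y": pair.second},
        known_ids=matrix.gene_ids,
        meta={"plot": "litre", "pair": [pair.first, pair.second]},
    )
    return fig


def litre_points_for_gene(
    matrix: ExpressionMatrix, pair: TreatmentPair, gene_id: str
) -> list[tuple[str, float, float]]:
    """One gene's m·n combination points (the foreground of one step)."""
    return _combination_points(matrix, pair, [matrix.gene_index(gene_id)])


def order_genes(
    metrics: MetricsTable, metric: str, order: str = "increasing"
) -> GeneIterator:
    """Sort genes by a metric to fix the overlay tour; ties break by gene id."""
    if order not in ("increasing", "decreasing"):
        raise ValidationError(
            f"order must be 'increasing' or 'decreasing', got {order!r}"
        )
    values = metrics.values(metric)  # raises UnknownIdError on bad metric
    ids = np.asarray(metrics.gene_ids)
    id_order = np.argsort(ids, kind="stable")
    sign = 1.0 if order == "increasing" else -1.0
    by_metric = np.argsort(sign * values[id_order], kind="stable")
    return GeneIterator(tuple(str(g) for g in ids[id_order][by_metric]), metric, order)


def plot_next_gene(
    fig: LayeredFigure,
    iterator: GeneIterator,
    matrix: ExpressionMatrix,
) -> tuple[LayeredFigure, GeneIterator]:
    """Overlay the next gene in metric order, replacing the previous overlay.

    The background hexbin is untouched (its build count stays at whatever it
    was); an exhausted iterator raises :class:`IteratorExhausted` and leaves
    the figure unchanged.
    """
    gene = iterator.current  # raises IteratorExhausted when done
    pair_names = fig.meta.get("pair")
    if pair_names is None:
        raise ValidationError("figure was not built by build_litre_background")
    pair = TreatmentPair(*pair_names)
    points = litre_points_for_gene(matrix, pair, gene)
    overlay = ForegroundLayer.points(
        points, hover={pid: gene for pid, _, _ in points}, color=engine.PINK
    )
    new_fig = engine.update_foreground(fig, overlay)
    return new_fig, replace(iterator, cursor=iterator.cursor + 1)
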