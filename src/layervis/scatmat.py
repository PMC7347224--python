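"""All-pairwise-samples scatterplot matrix with hexbin backgrounds.

n samples give an n × n grid: label-only diagonal panels and, for every
ordered sample pair (i, j), a hexagon background over the points
(count of gene g in sample i, count in sample j) for all genes.  Clicking a
background hexagon in any panel overlays that hexagon's member genes as
foreground points in *every* panel, each at that panel's own coordinates;
backgrounds are never rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import engine
from .core import ExpressionMatrix, GeneList
from .engine import ForegroundLayer, LayerSession, LayeredFigure
from .errors import UnknownIdError, ValidationError
from .hexgrid import hex_members

__all__ = ["DiagonalPanel", "PanelGrid", "build_scatmat", "click_hexagon", "overlay_gene_list"]


@dataclass(frozen=True)
class DiagonalPanel:
    """A diagonal cell of the matrix: carries the sample label only."""

    label: str


@dataclass
class PanelGrid:
    """The n × n panel grid; off-diagonal panels share one foreground gene set."""

    samples: tuple[str, ...]
    panels: dict[tuple[str, str], LayeredFigure | DiagonalPanel]
    matrix: ExpressionMatrix = field(repr=False)
    session: LayerSession = field(repr=False)
    log_transform: bool = False
    foreground_ids: tuple[str, ...] = ()

    @property
    def n_panels(self) -> int:
        return len(self.panels)

    def panel(self, row_sample: str, col_sample: str) -> LayeredFigure | DiagonalPanel:
        key = (row_sample, col_sample)
        if key not in self.panels:
            raise UnknownIdError(
                f"no panel for sample pair {key!r}; samples: {list(self.samples)}"
            )
        return self.panels[key]

    def scatter_panels(self) -> dict[tuple[str, str], LayeredFigure]:
        return {
            k: v for k, v in self.panels.items() if isinstance(v, LayeredFigure)
        }


def _panel_values(
    matrix: ExpressionMatrix, sample: str, log_transform: bool
) -> np.ndarray:
    vals = np.asarray(matrix.counts)[:, matrix.sample_index(sample)]
    return np.log2(vals + 1.0) if log_transform else vals


def build_scatmat(
    matrix: ExpressionMatrix,
    samples: Sequence[str] | None = None,
    n_bins: int = 10,
    log_transform: bool = False,
    session: LayerSession | None = None,
) -> PanelGrid:
    """Build the full n² panel grid with one hexbin background per scatter panel.

    Each panel computes its own hex grid from its own 2-D extent (per-panel
    extents differ; a shared grid would distort sparse panels).  The optional
    log2(count + 1) axis transform is off by default.
    """
    samples = tuple(samples) if samples is not None else tuple(matrix.sample_labels)
    if len(samples) < 2:
        raise ValidationError(f"need at least 2 samples for a scatterplot matrix, got {len(samples)}")
    for s in samples:
        matrix.sample_index(s)  # raises on unknown sample
    session = session or LayerSession()
    columns = {s: _panel_values(matrix, s, log_transform) for s in samples}
    panels: dict[tuple[str, str], LayeredFigure | DiagonalPanel] = {}
    for row in samples:
        for col in samples:
            if row == col:
                panels[(row, col)] = DiagonalPanel(row)
                continue
            points = list(zip(matrix.gene_ids, columns[col], columns[row]))
            panels[(row, col)] = engine.build_background(
                points,
                geom="hexagon",
                n_bins=n_bins,
                session=session,
                axes={"x": col, "y": row},
                known_ids=matrix.gene_ids,
                meta={"panel": [row, col]},
            )
    return PanelGrid(samples, panels, matrix, session, log_transform)


def _overlay_everywhere(grid: PanelGrid, gene_ids: Sequence[str], color: str) -> PanelGrid:
    gene_ids = tuple(gene_ids)
    GeneList.of(gene_ids).resolve(grid.matrix)
    rows = [grid.matrix.gene_index(g) for g in gene_ids]
    for (row, col), panel in grid.panels.items():
        if isinstance(panel, DiagonalPanel):
            continue
        xs = _panel_values(grid.matrix, col, grid.log_transform)[rows]
        ys = _panel_values(grid.matrix, row, grid.log_transform)[rows]
        overlay = ForegroundLayer.points(
            list(zip(gene_ids, xs, ys)), color=color
        )
        grid.panels[(row, col)] = engine.update_foreground(panel, overlay)
    grid.foreground_ids = gene_ids
    return grid


def click_hexagon(
    grid: PanelGrid, panel: tuple[str, str], hex_id: str
) -> PanelGrid:
    """Overlay the clicked hexagon's member genes in every panel (orange points).

    The click targets the background layer; the overlay replaces any previous
    foreground, and no background is rebuilt (build counters unchanged).
    """
    fig = grid.panel(*panel)
    if isinstance(fig, DiagonalPanel):
        raise UnknownIdError(f"panel {panel!r} is a diagonal label panel")
    members = hex_members(fig.background.payload, hex_id)
    return _overlay_everywhere(grid, members, engine.ORANGE)


def overlay_gene_list(grid: PanelGrid, genes: GeneList) -> PanelGrid:
    """Overlay an explicit gene subset (DEGs, a saved cluster) in every panel."""
    return _overlay_everywhere(grid, tuple(genes), engine.ORANGE)
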