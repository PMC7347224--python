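"""Volcano plots: significance vs fold change with threshold-driven overlays.

x is the log2 fold change, y is −log10 of the chosen significance column
(PValue by default; FDR selectable).  The background hexbins all genes in the
metrics table; the foreground overlays the genes passing
|logFC| ≥ lfc_min AND significance ≤ sig_max, replacing the previous overlay
whenever the thresholds change.  A significance of exactly 0 is clipped to
the smallest positive normal double before the log, so the most significant
genes keep a finite, top-ranked y.
"""

from __future__ import annotations

import numpy as np

from . import engine
from .core import MetricsTable, select_subset
from .engine import ForegroundLayer, LayerSession, LayeredFigure
from .errors import ValidationError

__all__ = [
    "volcano_coordinates",
    "build_volcano_background",
    "threshold_overlay",
    "set_overlay_style",
]

_SIG_FLOOR = float(np.finfo(float).tiny)


def volcano_coordinates(
    metrics: MetricsTable, sig_column: str = "PValue"
) -> tuple[np.ndarray, np.ndarray]:
    """(logFC, −log10 sig) for every gene, after zero-significance clipping."""
    x = metrics.values("logFC")
    sig = np.clip(metrics.values(sig_column), _SIG_FLOOR, None)
    return x, -np.log10(sig)


def build_volcano_background(
    metrics: MetricsTable,
    n_bins: int = 10,
    sig_column: str = "PValue",
    session: LayerSession | None = None,
) -> LayeredFigure:
    """Hexbin all genes in (logFC, −log10 sig) space; hover gives gene counts."""
    x, y = volcano_coordinates(metrics, sig_column)
    points = list(zip(metrics.gene_ids, x, y))
    return engine.build_background(
        points,
        geom="hexagon",
        n_bins=n_bins,
        session=session or LayerSession(),
        axes={"x": "log2 fold change", "y": f"-log10 {sig_column}"},
        known_ids=metrics.gene_ids,
        meta={"plot": "volcano", "sig_column": sig_column},
    )


def threshold_overlay(
    fig: LayeredFigure,
    metrics: MetricsTable,
    lfc_min: float,
    sig_max: float,
    sig_column: str = "PValue",
    point_size: float = 2.0,
) -> LayeredFigure:
    """Overlay genes with |logFC| ≥ lfc_min and significance ≤ sig_max.

    Exactly ``select_subset(logFC abs_ge lfc_min) ∩ select_subset(sig le
    sig_max)``; the background hexbin is untouched and repeated calls with
    new thresholds replace the overlay.
    """
    if lfc_min < 0:
        raise ValidationError(f"lfc_min must be nonnegative, got {lfc_min}")
    if not 0.0 < sig_max <= 1.0:
        raise ValidationError(f"sig_max must lie in (0, 1], got {sig_max}")
    by_lfc = set(select_subset(metrics, "logFC", lfc_min, "abs_ge"))
    by_sig = set(select_subset(metrics, sig_column, sig_max, "le"))
    keep = by_lfc & by_sig
    x, y = volcano_coordinates(metrics, sig_column)
    coords = [
        (g, float(xv), float(yv))
        for g, xv, yv in zip(metrics.gene_ids, x, y)
        if g in keep
    ]
    overlay = ForegroundLayer.points(coords, point_size=point_size, color=engine.PINK)
    return engine.update_foreground(fig, overlay)


def set_overlay_style(fig: LayeredFigure, point_size: float) -> LayeredFigure:
    """Style-only change: resize overlay points, gene set and background fixed."""
    if point_size <= 0:
        raise ValidationError(f"point size must be positive, got {point_size}")
    return engine.update_foreground(
        fig, fig.foreground.with_style(point_size=float(point_size))
    )
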