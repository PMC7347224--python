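"""The two-layer figure engine.

A :class:`LayeredFigure` is a background layer (the expensive part: a hexbin
or point cloud of *all* genes, with hover metadata) plus a foreground layer
(the cheap part: an overlay of a gene subset, with hover gene names).  The
engine's contract is that foreground updates never recompute the background:
backgrounds are built once per (data, geom, parameters) key and cached on a
:class:`LayerSession`, whose ``build_log`` counts constructions per key.
"Redrawing" is operationalized as payload recomputation — the figure's unit
of output is a deterministic JSON payload document, and the background
section of that document is byte-identical across any number of foreground
updates.

Rendering that payload to an interactive page or a static image lives in
:mod:`layervis.export`; zoom/pan are rendering-level concerns and never touch
layer data.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import UnknownIdError, ValidationError
from .hexgrid import HexLayer, bin_points, make_grid

__all__ = [
    "LayerSession",
    "BackgroundLayer",
    "ForegroundLayer",
    "LayeredFigure",
    "build_background",
    "update_foreground",
    "hover",
    "to_payload",
    "payload_json",
    "background_digest",
    "count_text",
]

PAYLOAD_VERSION = 1

#: Default overlay styles; pink foreground points echo the package's figures,
#: orange is used by scatterplot-matrix click overlays.
PINK = "#FF69B4"
ORANGE = "#FFA500"


def count_text(count: int) -> str:
    """Hover text for a hexagon's gene count ('1 gene', '19 genes')."""
    return f"{count} gene" if count == 1 else f"{count} genes"


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()


class LayerSession:
    """Per-session background cache and build log.

    ``build_log[key]`` counts how many times the background for ``key`` was
    actually constructed; the layer-independence contract is that it stays at
    1 however many foreground updates follow.
    """

    def __init__(self) -> None:
        self._cache: dict[str, BackgroundLayer] = {}
        self.build_log: Counter[str] = Counter()

    def get_or_build(self, cache_key: str, builder) -> "BackgroundLayer":
        if cache_key not in self._cache:
            self._cache[cache_key] = builder()
            self.build_log[cache_key] += 1
        return self._cache[cache_key]


_DEFAULT_SESSION = LayerSession()


def default_session() -> LayerSession:
    return _DEFAULT_SESSION


@dataclass(frozen=True)
class BackgroundLayer:
    """Immutable background: geom kind, payload document, hover map, cache key."""

    geom: str  # "hexagon" | "point" | "summary"
    payload: object  # HexLayer for hexagons; raw structures otherwise
    payload_doc: dict  # canonical serializable form (the unit under test)
    hover: Mapping[str, str]
    cache_key: str

    @property
    def digest(self) -> str:
        return _digest(self.payload_doc)


@dataclass(frozen=True)
class ForegroundLayer:
    """Overlay points or polylines for a gene subset, with hover gene names."""

    kind: str = "points"  # "points" | "polylines"
    elements: tuple = ()  # per element: {"id": str, "x": .., "y": ..} or {"id", "path"}
    hover: Mapping[str, str] = field(default_factory=dict)
    style: Mapping[str, object] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "ForegroundLayer":
        return cls()

    @classmethod
    def points(
        cls,
        coords: Sequence[tuple[str, float, float]],
        hover: Mapping[str, str] | None = None,
        point_size: float = 2.0,
        alpha: float = 1.0,
        color: str = PINK,
    ) -> "ForegroundLayer":
        elements = tuple(
            {"id": str(pid), "x": float(x), "y": float(y)} for pid, x, y in coords
        )
        if hover is None:
            hover = {e["id"]: e["id"] for e in elements}
        return cls(
            "points",
            elements,
            dict(hover),
            {"point_size": float(point_size), "alpha": float(alpha), "color": color},
        )

    @classmethod
    def polylines(
        cls,
        paths: Sequence[tuple[str, Sequence[tuple[float, float]]]],
        hover: Mapping[str, str] | None = None,
        alpha: float = 0.6,
        color: str = PINK,
        width: float = 1.0,
    ) -> "ForegroundLayer":
        elements = tuple(
            {"id": str(gid), "path": [[float(x), float(y)] for x, y in path]}
            for gid, path in paths
        )
        if hover is None:
            hover = {e["id"]: e["id"] for e in elements}
        return cls(
            "polylines",
            elements,
            dict(hover),
            {"alpha": float(alpha), "color": color, "width": float(width)},
        )

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(e["id"] for e in self.elements)

    def with_style(self, **updates) -> "ForegroundLayer":
        style = dict(self.style)
        style.update(updates)
        return replace(self, style=style)


@dataclass(frozen=True)
class LayeredFigure:
    """A background + foreground figure bound to its session's build log."""

    background: BackgroundLayer
    foreground: ForegroundLayer
    session: LayerSession = field(repr=False, compare=False)
    axes: Mapping[str, object] = field(default_factory=dict)
    known_ids: frozenset[str] | None = field(default=None, repr=False)
    meta: Mapping[str, object] = field(default_factory=dict, repr=False)

    @property
    def build_count(self) -> int:
        return self.session.build_log[self.background.cache_key]


def _hexagon_background(
    points: Sequence[tuple[str, float, float]],
    n_bins: int,
    pad_fraction: float,
) -> tuple[object, dict, dict]:
    ids = [p[0] for p in points]
    x = np.array([p[1] for p in points], dtype=float)
    y = np.array([p[2] for p in points], dtype=float)
    grid = make_grid(x, y, n_bins, pad_fraction)
    layer = bin_points(ids, x, y, grid)
    hover = {hid: count_text(b.count) for hid, b in layer.bins.items()}
    return layer, layer.to_dict(), hover


def _point_background(points: Sequence[tuple[str, float, float]]) -> tuple[object, dict, dict]:
    elements = [
        {"id": str(pid), "x": float(x), "y": float(y)} for pid, x, y in points
    ]
    hover = {e["id"]: e["id"] for e in elements}
    return tuple(elements), {"points": elements}, hover


def build_background(
    points: Sequence[tuple[str, float, float]],
    geom: str = "hexagon",
    n_bins: int = 10,
    pad_fraction: float = 0.05,
    session: LayerSession | None = None,
    axes: Mapping[str, object] | None = None,
    known_ids: Sequence[str] | None = None,
    meta: Mapping[str, object] | None = None,
) -> LayeredFigure:
    """Build (or fetch from cache) a background layer; foreground starts empty.

    The cache key digests the point data, geom and parameters, so a repeat
    build with identical inputs is served from the session cache and the
    build log is unchanged.
    """
    points = list(points)
    if not points:
        raise ValidationError("cannot build a background from an empty point set")
    if geom not in ("hexagon", "point"):
        raise ValidationError(f"geom must be 'hexagon' or 'point', got {geom!r}")
    session = session or default_session()
    data_key = _digest(
        [[str(p[0]), float(p[1]), float(p[2])] for p in points]
    )
    params = {"geom": geom, "n_bins": n_bins, "pad_fraction": pad_fraction}
    cache_key = _digest({"data": data_key, "params": params})

    def builder() -> BackgroundLayer:
        if geom == "hexagon":
            payload, doc, hover_map = _hexagon_background(points, n_bins, pad_fraction)
        else:
            payload, doc, hover_map = _point_background(points)
        return BackgroundLayer(geom, payload, doc, hover_map, cache_key)

    background = session.get_or_build(cache_key, builder)
    return LayeredFigure(
        background=background,
        foreground=ForegroundLayer.empty(),
        session=session,
        axes=dict(axes or {}),
        known_ids=frozenset(known_ids) if known_ids is not None else None,
        meta=dict(meta or {}),
    )


def summary_background(
    doc: dict,
    hover: Mapping[str, str],
    cache_key_seed: object,
    session: LayerSession | None = None,
    axes: Mapping[str, object] | None = None,
    known_ids: Sequence[str] | None = None,
    meta: Mapping[str, object] | None = None,
) -> LayeredFigure:
    """Background variant for non-binned aggregates (five-number-summary boxes)."""
    session = session or default_session()
    cache_key = _digest({"summary": cache_key_seed})
    background = session.get_or_build(
        cache_key,
        lambda: BackgroundLayer("summary", doc, doc, dict(hover), cache_key),
    )
    return LayeredFigure(
        background=background,
        foreground=ForegroundLayer.empty(),
        session=session,
        axes=dict(axes or {}),
        known_ids=frozenset(known_ids) if known_ids is not None else None,
        meta=dict(meta or {}),
    )


def update_foreground(fig: LayeredFigure, overlay: ForegroundLayer) -> LayeredFigure:
    """Replace the foreground; the background object is reused untouched.

    Overlay gene ids must resolve against the figure's source data; an absent
    id is an error rather than a silent drop.
    """
    if fig.known_ids is not None:
        # polyline/point element ids may suffix-tag replicate combinations;
        # the resolvable unit is the hover target (the gene id)
        unknown = [g for g in overlay.hover.values() if g not in fig.known_ids]
        if unknown:
            raise UnknownIdError(
                f"overlay genes absent from source data: {sorted(set(unknown))[:5]}"
            )
    return replace(fig, foreground=overlay)


def hover(fig: LayeredFigure, layer: str, geom_id: str) -> str:
    """Hover text: hexagon → gene count, foreground element → gene name."""
    if layer == "background":
        table = fig.background.hover
    elif layer == "foreground":
        table = fig.foreground.hover
    else:
        raise ValidationError(f"layer must be 'background' or 'foreground', got {layer!r}")
    if geom_id not in table:
        raise UnknownIdError(f"no geom {geom_id!r} in the {layer} layer")
    return table[geom_id]


def to_payload(fig: LayeredFigure) -> dict:
    """The figure's deterministic, serializable description."""
    return {
        "version": PAYLOAD_VERSION,
        "axes": dict(fig.axes),
        "background": {
            "geom": fig.background.geom,
            "data": fig.background.payload_doc,
            "hover": dict(fig.background.hover),
        },
        "foreground": {
            "kind": fig.foreground.kind,
            "elements": list(fig.foreground.elements),
            "hover": dict(fig.foreground.hover),
            "style": dict(fig.foreground.style),
        },
    }


def payload_json(fig: LayeredFigure) -> str:
    """Canonical JSON text of the payload: stable key order, byte-identical
    across repeated serialization of the same figure."""
    return json.dumps(to_payload(fig), sort_keys=True, separators=(",", ":"))


def background_digest(fig: LayeredFigure) -> str:
    """Digest of the background section of the payload (the redraw detector)."""
    return _digest(to_payload(fig)["background"])
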