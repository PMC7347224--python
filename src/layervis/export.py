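"""Export of figures: payload JSON, static PNG/JPG, minimal interactive HTML,
gene-list text files, and run manifests.

All text artifacts are written atomically (write to a temp name in the target
directory, then rename) so no output file is ever partially written on error.
The payload JSON is the engine's unit of output; the PNG renderer draws the
hexagon Voronoi cells, overlay points/polylines and summary boxes with
matplotlib, and the HTML export is a small self-contained viewer that embeds
the payload JSON and renders it to SVG with hover titles.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection, PolyCollection

from .engine import LayeredFigure, payload_json

__all__ = [
    "atomic_write_text",
    "write_payload",
    "write_png",
    "write_html",
    "write_gene_list",
    "sha256_of",
    "write_manifest",
]


def atomic_write_text(path: str | Path, text: str) -> Path:
    """Write text to a temp file in the same directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_payload(fig: LayeredFigure, path: str | Path) -> Path:
    return atomic_write_text(path, payload_json(fig) + "\n")


def write_gene_list(ids: Sequence[str], path: str | Path) -> Path:
    return atomic_write_text(path, "".join(f"{g}\n" for g in ids))


def _hexagon_vertices(cx: float, cy: float, w: float, h: float) -> list[tuple[float, float]]:
    """Voronoi cell of the dual-offset lattice: pointy-top hexagon vertices.

    Side vertices sit at x = ±w/2, y = ±(h² − w²)/(4h); top/bottom at
    (0, ±(w² + h²)/(4h)).  For h = √3·w this is the regular hexagon.
    """
    ys = (h * h - w * w) / (4.0 * h)
    yt = (w * w + h * h) / (4.0 * h)
    return [
        (cx, cy + yt),
        (cx + w / 2, cy + ys),
        (cx + w / 2, cy - ys),
        (cx, cy - yt),
        (cx - w / 2, cy - ys),
        (cx - w / 2, cy + ys),
    ]


def render_figure(fig: LayeredFigure, ax=None):
    """Draw one layered figure onto a matplotlib Axes (created if missing)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    bg = fig.background
    if bg.geom == "hexagon":
        doc = bg.payload_doc
        w = doc["grid"]["hex_width"]
        h = doc["grid"]["hex_height"]
        counts = [b["count"] for b in doc["bins"]]
        polys = [
            _hexagon_vertices(b["center"][0], b["center"][1], w, h)
            for b in doc["bins"]
        ]
        coll = PolyCollection(polys, array=counts, cmap="viridis", edgecolors="none")
        ax.add_collection(coll)
        ax.set_xlim(*doc["grid"]["x_range"])
        ax.set_ylim(*doc["grid"]["y_range"])
        plt.colorbar(coll, ax=ax, label="genes per hexagon")
    elif bg.geom == "point":
        xs = [p["x"] for p in bg.payload_doc["points"]]
        ys = [p["y"] for p in bg.payload_doc["points"]]
        ax.plot(xs, ys, ".", color="#555555", ms=2, alpha=0.5)
    elif bg.geom == "summary":
        for box in bg.payload_doc.get("boxes", []):
            x = box["position"]
            ax.plot([x, x], [box["min"], box["max"]], color="#999999", lw=1)
            ax.add_patch(
                plt.Rectangle(
                    (x - 0.2, box["q1"]), 0.4, box["q3"] - box["q1"],
                    facecolor="#DDDDDD", edgecolor="#777777",
                )
            )
            ax.plot([x - 0.2, x + 0.2], [box["median"]] * 2, color="#333333", lw=1.5)
        ax.autoscale_view()
    fg = fig.foreground
    style = dict(fg.style)
    if fg.kind == "points" and fg.elements:
        xs = [e["x"] for e in fg.elements]
        ys = [e["y"] for e in fg.elements]
        ax.plot(
            xs, ys, "o",
            color=style.get("color", "#FF69B4"),
            ms=2 * style.get("point_size", 2.0),
            alpha=style.get("alpha", 1.0),
            mec="none",
        )
    elif fg.kind == "polylines" and fg.elements:
        segs = [e["path"] for e in fg.elements]
        ax.add_collection(
            LineCollection(
                segs,
                colors=style.get("color", "#FF69B4"),
                alpha=style.get("alpha", 0.6),
                linewidths=style.get("width", 1.0),
            )
        )
        ax.autoscale_view()
    ax.set_xlabel(str(fig.axes.get("x", "")))
    ax.set_ylabel(str(fig.axes.get("y", "")))
    return ax


def write_png(fig: LayeredFigure, path: str | Path, dpi: int = 150) -> Path:
    """Static image export (PNG or JPG by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ax = render_figure(fig)
    ax.figure.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(ax.figure)
    return path


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>layervis figure</title></head>
<body>
<svg id="fig" width="720" height="560" style="border:1px solid #ccc"></svg>
<script>
const payload = {payload};
const svg = document.getElementById('fig');
const NS = 'http://www.w3.org/2000/svg';
function el(tag, attrs, title) {{
  const e = document.createElementNS(NS, tag);
  for (const [k, v] of Object.entries(attrs)) e.setAttribute(k, v);
  if (title) {{ const t = document.createElementNS(NS, 'title'); t.textContent = title; e.appendChild(t); }}
  svg.appendChild(e); return e;
}}
let xr = [0, 1], yr = [0, 1];
const bg = payload.background;
if (bg.geom === 'hexagon') {{ xr = bg.data.grid.x_range; yr = bg.data.grid.y_range; }}
else {{
  const pts = [];
  if (bg.geom === 'point') bg.data.points.forEach(p => pts.push([p.x, p.y]));
  if (bg.geom === 'summary') bg.data.boxes.forEach(b => {{ pts.push([b.position, b.min]); pts.push([b.position, b.max]); }});
  payload.foreground.elements.forEach(e => {{
    if (e.path) e.path.forEach(q => pts.push(q)); else pts.push([e.x, e.y]);
  }});
  if (pts.length) {{
    xr = [Math.min(...pts.map(p=>p[0]))-1, Math.max(...pts.map(p=>p[0]))+1];
    yr = [Math.min(...pts.map(p=>p[1]))-1, Math.max(...pts.map(p=>p[1]))+1];
  }}
}}
const sx = x => 40 + (x - xr[0]) / (xr[1] - xr[0]) * 640;
const sy = y => 520 - (y - yr[0]) / (yr[1] - yr[0]) * 480;
if (bg.geom === 'hexagon') {{
  const w = bg.data.grid.hex_width, h = bg.data.grid.hex_height;
  const maxc = Math.max(...bg.data.bins.map(b => b.count));
  for (const b of bg.data.bins) {{
    const [cx, cy] = b.center;
    const yside = (h*h - w*w) / (4*h), ytop = (w*w + h*h) / (4*h);
    const v = [[cx, cy+ytop],[cx+w/2, cy+yside],[cx+w/2, cy-yside],[cx, cy-ytop],[cx-w/2, cy-yside],[cx-w/2, cy+yside]];
    const shade = Math.round(230 - 180 * b.count / maxc);
    el('polygon', {{points: v.map(p => sx(p[0]) + ',' + sy(p[1])).join(' '),
                   fill: 'rgb(' + shade + ',' + shade + ',255)'}}, bg.hover[b.id]);
  }}
}} else if (bg.geom === 'point') {{
  for (const p of bg.data.points) el('circle', {{cx: sx(p.x), cy: sy(p.y), r: 2, fill: '#888'}}, bg.hover[p.id]);
}} else if (bg.geom === 'summary') {{
  for (const b of bg.data.boxes) {{
    el('line', {{x1: sx(b.position), x2: sx(b.position), y1: sy(b.min), y2: sy(b.max), stroke: '#999'}}, bg.hover[b.axis]);
    el('rect', {{x: sx(b.position) - 8, y: sy(b.q3), width: 16, height: sy(b.q1) - sy(b.q3), fill: '#ddd', stroke: '#777'}}, bg.hover[b.axis]);
  }}
}}
const fgs = payload.foreground.style;
for (const e of payload.foreground.elements) {{
  const hovertext = payload.foreground.hover[e.id] || e.id;
  if (payload.foreground.kind === 'points')
    el('circle', {{cx: sx(e.x), cy: sy(e.y), r: 1.5 * (fgs.point_size || 2),
                   fill: fgs.color || '#FF69B4', 'fill-opacity': fgs.alpha || 1}}, hovertext);
  else
    el('polyline', {{points: e.path.map(p => sx(p[0]) + ',' + sy(p[1])).join(' '),
                    fill: 'none', stroke: fgs.color || '#FF69B4',
                    'stroke-opacity': fgs.alpha || 0.6}}, hovertext);
}}
</script>
</body></html>
"""


def write_html(fig: LayeredFigure, path: str | Path) -> Path:
    """Self-contained HTML viewer embedding the payload JSON (hover via titles)."""
    return atomic_write_text(path, _HTML_TEMPLATE.format(payload=payload_json(fig)))


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    directory: str | Path,
    files: Sequence[Path],
    parameters: Mapping[str, object],
) -> Path:
    """Manifest of every written artifact with digests plus the parameter echo."""
    directory = Path(directory)
    entries = [
        {"path": str(Path(f).relative_to(directory)), "sha256": sha256_of(f)}
        for f in files
    ]
    doc = {"parameters": dict(parameters), "files": entries}
    return atomic_write_text(
        directory / "manifest.json", json.dumps(doc, sort_keys=True, indent=2) + "\n"
    )
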