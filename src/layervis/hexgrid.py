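"""Hexagonal binning with exact reverse membership.

The lattice is the classic Carr construction used by hexbin geoms: two
interleaved rectangular lattices of hexagon centers, the second offset by half
a spacing in both x and y, with each point assigned to the nearest center
under a Euclidean distance scaled by (hex_width, hex_height).  The Voronoi
cells of that union of lattices are hexagons, so nearest-center assignment is
hexagonal tessellation.  Unlike the usual rendering-oriented hexbin, each bin
records *which* points it contains, so a hexagon can be queried for its member
genes (the hover/click contract of the layered figures).

Geometry: ``hex_width`` is the horizontal center spacing (span(x)/n_bins, the
single user-facing "hexagon size" control); ``hex_height`` is the vertical
spacing within one sublattice, ``hex_width * (span(y)/span(x)) * sqrt(3)``,
which makes the cells regular pointy-top hexagons when the two axis ranges are
displayed at equal size.  Offset rows therefore sit at half that spacing.

Ties on a perpendicular bisector break toward the lexicographically smaller
center (lower-left), so binning is deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import UnknownIdError, ValidationError

__all__ = ["HexGridSpec", "HexBin", "HexLayer", "make_grid", "bin_points", "hex_members"]

_ASPECT = math.sqrt(3.0)


@dataclass(frozen=True)
class HexGridSpec:
    """Lattice geometry: padded data ranges plus derived hexagon spacings."""

    x_range: tuple[float, float]
    y_range: tuple[float, float]
    n_bins: int
    hex_width: float
    hex_height: float

    def center_of(self, hex_id: str) -> tuple[float, float]:
        """Data-space center of a hexagon id (doubled-lattice integer coords)."""
        qi, qj = _parse_hex_id(hex_id)
        return (
            self.x_range[0] + 0.5 * qi * self.hex_width,
            self.y_range[0] + 0.5 * qj * self.hex_height,
        )


def _parse_hex_id(hex_id: str) -> tuple[int, int]:
    try:
        qi_text, qj_text = hex_id.split(":")
        return int(qi_text), int(qj_text)
    except (ValueError, AttributeError):
        raise UnknownIdError(f"malformed hexagon id {hex_id!r}") from None


@dataclass(frozen=True)
class HexBin:
    hex_id: str
    center: tuple[float, float]
    count: int
    members: tuple[str, ...]


@dataclass(frozen=True)
class HexLayer:
    """Binned points: per-hexagon counts and members, plus the reverse map."""

    grid: HexGridSpec
    bins: Mapping[str, HexBin]  # insertion order = first-appearance order
    point_to_hex: Mapping[str, str]

    @property
    def total_count(self) -> int:
        return sum(b.count for b in self.bins.values())

    def to_dict(self) -> dict:
        """Documented JSON schema: grid spec + per-bin id/center/count/members."""
        return {
            "grid": {
                "x_range": list(self.grid.x_range),
                "y_range": list(self.grid.y_range),
                "n_bins": self.grid.n_bins,
                "hex_width": self.grid.hex_width,
                "hex_height": self.grid.hex_height,
            },
            "bins": [
                {
                    "id": b.hex_id,
                    "center": list(b.center),
                    "count": b.count,
                    "members": list(b.members),
                }
                for b in self.bins.values()
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def make_grid(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int,
    pad_fraction: float = 0.05,
) -> HexGridSpec:
    """Build the lattice spec from a point cloud's extent.

    Ranges are the data extent expanded by ``pad_fraction`` of the span on each
    side; a degenerate extent (all values equal) expands to a unit interval
    centered on the point.  ``span(x_range) = hex_width * n_bins`` exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot build a hex grid from an empty point set")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")

    def padded(vals: np.ndarray) -> tuple[float, float]:
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            return lo - 0.5, hi + 0.5
        pad = pad_fraction * (hi - lo)
        return lo - pad, hi + pad

    x_range, y_range = padded(x), padded(y)
    hex_width = (x_range[1] - x_range[0]) / n_bins
    hex_height = hex_width * ((y_range[1] - y_range[0]) / (x_range[1] - x_range[0])) * _ASPECT
    return HexGridSpec(x_range, y_range, n_bins, hex_width, hex_height)


def _assign(
    x: np.ndarray, y: np.ndarray, grid: HexGridSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Doubled-lattice integer coordinates (qi, qj) of the nearest center.

    Sublattice A centers sit at (i*W, j*H) from the range origin, sublattice B
    at ((i+1/2)*W, (j+1/2)*H); in doubled coordinates A is (2i, 2j), B is
    (2i+1, 2j+1).  Nearest center within a rectangular sublattice is
    per-coordinate rounding, so only two candidates need comparing.
    """
    u = (x - grid.x_range[0]) / grid.hex_width
    v = (y - grid.y_range[0]) / grid.hex_height
    # ceil(t - 0.5) is nearest-integer with exact halves going DOWN, so a point
    # equidistant between two centers of one sublattice takes the lower-left one
    ia, ja = np.ceil(u - 0.5), np.ceil(v - 0.5)
    ib, jb = np.ceil(u - 1.0), np.ceil(v - 1.0)
    da = (u - ia) ** 2 + (v - ja) ** 2
    db = (u - ib - 0.5) ** 2 + (v - jb - 0.5) ** 2
    # tie -> lexicographically smaller (center_x, center_y), i.e. lower-left
    a_first = np.where(
        da != db,
        da < db,
        (ia < ib + 0.5) | ((ia == ib + 0.5) & (ja <= jb + 0.5)),
    )
    qi = np.where(a_first, 2 * ia.astype(np.int64), 2 * ib.astype(np.int64) + 1)
    qj = np.where(a_first, 2 * ja.astype(np.int64), 2 * jb.astype(np.int64) + 1)
    return qi, qj


def bin_points(
    point_ids: Sequence[str],
    x: Sequence[float],
    y: Sequence[float],
    grid: HexGridSpec,
) -> HexLayer:
    """Assign every point to its nearest hexagon center; empty bins are not stored.

    Bin order is first-appearance order of the input points, so repeated
    binning of the same input is byte-identical.
    """
    point_ids = [str(p) for p in point_ids]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(point_ids) == x.size == y.size):
        raise ValidationError("point ids and coordinates differ in length")
    if len(set(point_ids)) != len(point_ids):
        raise ValidationError("point ids must be unique within one binning")
    out_x = (x < grid.x_range[0]) | (x > grid.x_range[1])
    out_y = (y < grid.y_range[0]) | (y > grid.y_range[1])
    outside = out_x | out_y
    if outside.any():
        k = int(np.argmax(outside))
        raise ValidationError(
            f"point {point_ids[k]!r} at ({x[k]}, {y[k]}) lies outside the grid ranges"
        )
    qi, qj = _assign(x, y, grid)
    bins: dict[str, list[str]] = {}
    point_to_hex: dict[str, str] = {}
    for pid, i, j in zip(point_ids, qi.tolist(), qj.tolist()):
        hex_id = f"{i}:{j}"
        bins.setdefault(hex_id, []).append(pid)
        point_to_hex[pid] = hex_id
    built = {
        hid: HexBin(hid, grid.center_of(hid), len(members), tuple(members))
        for hid, members in bins.items()
    }
    return HexLayer(grid, built, point_to_hex)


def hex_members(layer: HexLayer, hex_id: str) -> list[str]:
    """Members of one hexagon, in input order; unknown ids are an error."""
    if hex_id not in layer.bins:
        raise UnknownIdError(f"hexagon {hex_id!r} not present in this layer")
    return list(layer.bins[hex_id].members)
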