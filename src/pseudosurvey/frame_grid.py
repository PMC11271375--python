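"""Sample frames and area-derived hexagonal grids.

The target population of an estuarine condition assessment is represented by a
*sample frame*: one or more planar polygons in an equal-area coordinate system.
Heterogeneous monitoring records are harmonized onto a regular hexagonal grid
whose cell size is derived from the frame area and the number of assessment
sites, so that one grid cell corresponds (in expectation) to the area one
design site will represent.

Two sizing conventions are supported:

``area_exact``
    each hexagon's area equals ``total_area / n_sites``;
``paper_spacing``
    the center-to-center spacing of adjacent cells equals
    ``2 * sqrt(total_area / n_sites)`` (the convention that reproduces the
    roughly 16 km spacing and 134-cell grid of the motivating 2705.9 km²
    Florida panhandle application; this is the default).

All coordinates are planar and expressed in kilometres internally.  Geographic
(longitude/latitude) input is rejected: areas are meaningless there and no
reprojection machinery is bundled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon, mapping, shape
from shapely.ops import unary_union

__all__ = [
    "CrsError",
    "FrameGridMismatchError",
    "SampleFrame",
    "HexCell",
    "HexGrid",
    "total_area",
    "make_hex_grid",
    "clip_grid",
    "assign_hex_id",
    "assign_hex_ids",
    "clipped_cell_areas",
]

_GEOGRAPHIC_HINTS = ("4326", "wgs84", "wgs 84", "geographic", "longlat", "lonlat")


class CrsError(ValueError):
    """Raised when coordinates are not in a usable equal-area planar CRS."""


class FrameGridMismatchError(ValueError):
    """Raised when a grid and a frame share no area at all."""


def _as_multipolygon(geom) -> MultiPolygon:
    geom = shapely.make_valid(geom)
    if geom.geom_type == "Polygon":
        geom = MultiPolygon([geom])
    elif geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        geom = _as_multipolygon(unary_union(polys)) if polys else MultiPolygon([])
    if geom.geom_type != "MultiPolygon":
        raise ValueError(f"frame geometry must be polygonal, got {geom.geom_type}")
    return geom


@dataclass(frozen=True)
class SampleFrame:
    """A resource polygon set in a planar equal-area CRS (coordinates in km).

    Parameters
    ----------
    geometry:
        A (Multi)Polygon; repaired with ``make_valid`` on construction.
    crs_id:
        Free-text identifier of the equal-area CRS the coordinates are in.
        Identifiers that look geographic (EPSG:4326, WGS84, ...) are rejected.
    """

    geometry: MultiPolygon
    crs_id: str = "local-equal-area-km"

    def __post_init__(self) -> None:
        low = self.crs_id.lower()
        if any(h in low for h in _GEOGRAPHIC_HINTS):
            raise CrsError(
                f"crs_id {self.crs_id!r} looks geographic; project the frame to an "
                "equal-area CRS (km or m) before constructing a SampleFrame"
            )
        geom = _as_multipolygon(self.geometry)
        if geom.is_empty or geom.area <= 0:
            raise ValueError("frame geometry is empty or has zero area")
        object.__setattr__(self, "geometry", geom)

    @classmethod
    def from_polygons(cls, polygons, crs_id: str = "local-equal-area-km",
                      unit: str = "km") -> "SampleFrame":
        """Build a frame from an iterable of polygons; ``unit`` is 'km' or 'm'."""
        geom = unary_union(list(polygons))
        return cls._scaled(geom, crs_id, unit)

    @classmethod
    def from_geojson(cls, path, crs_id: str = "local-equal-area-km",
                     unit: str = "km") -> "SampleFrame":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
            geom = unary_union(geoms)
        elif gj.get("type") == "Feature":
            geom = shape(gj["geometry"])
        else:
            geom = shape(gj)
        return cls._scaled(geom, crs_id, unit)

    @classmethod
    def _scaled(cls, geom, crs_id: str, unit: str) -> "SampleFrame":
        if unit == "m":
            geom = shapely.transform(geom, lambda c: c * 1e-3)
        elif unit != "km":
            raise ValueError(f"unit must be 'km' or 'm', got {unit!r}")
        return cls(geometry=_as_multipolygon(geom), crs_id=crs_id)

    @property
    def total_area(self) -> float:
        """Total frame area in km²."""
        return self.geometry.area

    @property
    def bounds(self):
        return self.geometry.bounds

    def to_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "type": "Feature",
                    "properties": {"crs_id": self.crs_id, "total_area_km2": self.total_area},
                    "geometry": mapping(self.geometry),
                },
                fh,
            )

    def contains_xy(self, x, y) -> np.ndarray:
        """Vectorized boundary-inclusive containment test."""
        inside = shapely.contains_xy(self.geometry, x, y)
        if np.all(inside):
            return np.asarray(inside)
        # include boundary points
        bnd = shapely.intersects(shapely.points(np.c_[np.atleast_1d(x), np.atleast_1d(y)]),
                                 self.geometry)
        return np.asarray(inside) | np.asarray(bnd).reshape(np.shape(inside))


def total_area(frame: SampleFrame) -> float:
    """Total frame area in km² (sum of polygon areas)."""
    return frame.total_area


@dataclass(frozen=True)
class HexCell:
    hex_id: str
    row: int
    col: int
    polygon: Polygon
    centroid: tuple
    intersects_frame: bool


@dataclass
class HexGrid:
    """A lattice of congruent regular hexagons covering (at least) a frame bbox.

    ``cell_spacing`` is the center-to-center distance of edge-adjacent cells
    (twice the apothem), in km.  Cell ids derive deterministically from the
    lattice (row, col) indices given origin, spacing and orientation.
    """

    cell_spacing: float
    orientation: str  # "flat" | "pointy"
    origin: tuple
    cells: list = field(default_factory=list)
    _tree: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ids = [c.hex_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate hex ids in grid")

    @property
    def cell_area(self) -> float:
        # regular hexagon: area = (sqrt(3)/2) * spacing^2
        return math.sqrt(3.0) / 2.0 * self.cell_spacing**2

    @property
    def circumradius(self) -> float:
        return self.cell_spacing / math.sqrt(3.0)

    def cell(self, hex_id: str) -> HexCell:
        for c in self.cells:
            if c.hex_id == hex_id:
                return c
        raise KeyError(hex_id)

    def _strtree(self):
        if self._tree is None:
            self._tree = shapely.STRtree([c.polygon for c in self.cells])
        return self._tree

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {
                    "hex_id": c.hex_id,
                    "row": c.row,
                    "col": c.col,
                    "intersects_frame": bool(c.intersects_frame),
                },
                "geometry": mapping(c.polygon),
            }
            for c in self.cells
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _hex_polygon(cx: float, cy: float, r: float, orientation: str) -> Polygon:
    # exact vertex offsets (half-spacing h = sqrt(3)/2 * r) avoid trig slivers
    h = math.sqrt(3.0) / 2.0 * r
    if orientation == "flat":
        pts = [(cx + r, cy), (cx + r / 2, cy + h), (cx - r / 2, cy + h),
               (cx - r, cy), (cx - r / 2, cy - h), (cx + r / 2, cy - h)]
    else:
        pts = [(cx, cy + r), (cx + h, cy + r / 2), (cx + h, cy - r / 2),
               (cx, cy - r), (cx - h, cy - r / 2), (cx - h, cy + r / 2)]
    return Polygon(pts)


def _lattice_center(row: int, col: int, origin, spacing: float, orientation: str):
    r = spacing / math.sqrt(3.0)
    if orientation == "flat":
        x = origin[0] + 1.5 * r * col
        y = origin[1] + spacing * row + (col % 2) * spacing / 2.0
    else:
        x = origin[0] + spacing * col + (row % 2) * spacing / 2.0
        y = origin[1] + 1.5 * r * row
    return x, y


def make_hex_grid(frame: SampleFrame, n_sites: int,
                  convention: str = "paper_spacing",
                  orientation: str = "flat") -> HexGrid:
    """Build a hexagonal grid sized from the frame area and a site count.

    The grid covers the frame's bounding box with one cell of margin; it is
    anchored at the lower-left corner of the bounding box.  ``intersects_frame``
    is evaluated per cell (boundary-inclusive).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if orientation not in ("flat", "pointy"):
        raise ValueError("orientation must be 'flat' or 'pointy'")
    area = frame.total_area
    if convention == "area_exact":
        cell_area = area / n_sites
        spacing = math.sqrt(2.0 * cell_area / math.sqrt(3.0))
    elif convention == "paper_spacing":
        spacing = 2.0 * math.sqrt(area / n_sites)
    else:
        raise ValueError(f"unknown sizing convention {convention!r}")

    minx, miny, maxx, maxy = frame.bounds
    origin = (minx, miny)
    r = spacing / math.sqrt(3.0)
    if orientation == "flat":
        ncol = int(math.ceil((maxx - minx) / (1.5 * r))) + 1
        nrow = int(math.ceil((maxy - miny) / spacing)) + 1
    else:
        ncol = int(math.ceil((maxx - minx) / spacing)) + 1
        nrow = int(math.ceil((maxy - miny) / (1.5 * r))) + 1

    shapely.prepare(frame.geometry)
    cells = []
    for row in range(-1, nrow + 1):
        for col in range(-1, ncol + 1):
            cx, cy = _lattice_center(row, col, origin, spacing, orientation)
            poly = _hex_polygon(cx, cy, r, orientation)
            hit = shapely.intersects(frame.geometry, poly)
            cells.append(
                HexCell(
                    hex_id=f"r{row}c{col}",
                    row=row,
                    col=col,
                    polygon=poly,
                    centroid=(cx, cy),
                    intersects_frame=bool(hit),
                )
            )
    return HexGrid(cell_spacing=spacing, orientation=orientation, origin=origin, cells=cells)


def clip_grid(grid: HexGrid, frame: SampleFrame) -> HexGrid:
    """Retain exactly the cells whose polygon intersects the frame (boundary counts)."""
    shapely.prepare(frame.geometry)
    kept = []
    for c in grid.cells:
        hit = bool(shapely.intersects(frame.geometry, c.polygon))
        if hit:
            kept.append(c if c.intersects_frame else replace(c, intersects_frame=True))
    if not kept:
        raise FrameGridMismatchError("no grid cell intersects the frame; grid/frame mismatch")
    return HexGrid(cell_spacing=grid.cell_spacing, orientation=grid.orientation,
                   origin=grid.origin, cells=kept)


def _resolve_candidates(grid: HexGrid, idxs, x: float, y: float) -> str | None:
    """Among candidate cell indices, pick the covering cell with lowest (row, col).

    A tolerance of 1e-9 cell spacings absorbs floating-point slivers on shared
    edges so boundary points always resolve to a cell.
    """
    pt = Point(x, y)
    tol = 1e-9 * grid.cell_spacing
    hits = [grid.cells[i] for i in idxs
            if grid.cells[i].polygon.covers(pt) or grid.cells[i].polygon.distance(pt) <= tol]
    if not hits:
        return None
    best = min(hits, key=lambda c: (c.row, c.col))
    return best.hex_id


def assign_hex_id(point, grid: HexGrid) -> str:
    """Id of the cell containing ``point``; edge ties break to the lower (row, col)."""
    x, y = float(point[0]), float(point[1])
    tree = grid._strtree()
    idxs = tree.query(Point(x, y), predicate="dwithin",
                      distance=1e-9 * grid.cell_spacing)
    hid = _resolve_candidates(grid, np.atleast_1d(idxs), x, y)
    if hid is None:
        raise ValueError(f"point ({x}, {y}) lies outside all grid cells")
    return hid


def assign_hex_ids(xy: np.ndarray, grid: HexGrid) -> list:
    """Vectorized :func:`assign_hex_id` for an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    pts = shapely.points(xy)
    tree = grid._strtree()
    pt_idx, cell_idx = tree.query(pts, predicate="dwithin",
                                  distance=1e-9 * grid.cell_spacing)
    cands: dict[int, list] = {}
    for p, c in zip(pt_idx, cell_idx):
        cands.setdefault(int(p), []).append(int(c))
    out = []
    for i in range(len(xy)):
        hid = None
        if i in cands:
            hid = _resolve_candidates(grid, cands[i], xy[i, 0], xy[i, 1])
        if hid is None:
            raise ValueError(f"point index {i} at {tuple(xy[i])} lies outside all grid cells")
        out.append(hid)
    return out


def clipped_cell_areas(grid: HexGrid, frame: SampleFrame) -> dict:
    """km² of cell∩frame per hex id (sums to the frame total over a clipped grid)."""
    return {c.hex_id: c.polygon.intersection(frame.geometry).area for c in grid.cells}
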