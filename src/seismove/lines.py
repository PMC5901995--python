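"""Seismic-line geometry and attribution.

Segments a polyline network into ~100-m pieces and attributes each piece
with the covariates the movement models use: mean vegetation height along
the least-cost (lowest-vegetation) path through a height raster (*Veght*),
an exponential-decay transform of depth-to-water (*eWAM*), the majority
landcover class (*fLand*), and line density in a moving window (*Density*).
Also provides nearest-segment distance queries for step endpoints and the
eDist decay transform.

All coordinates are planar metres. Rasters follow the Esri ASCII grid
convention: ``values[0, :]`` is the northernmost row, origin is the
lower-left corner, cells are addressed by ``floor((p - origin)/cell_size)``.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box
from shapely.ops import substring
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

# Decay constants (1/m): distance-to-line and depth-to-water influence scales.
EDIST_RATE = 0.002
EWAM_RATE = 1.55

#: Declared landcover class order; also the deterministic tie-break order.
LANDCOVER_CLASSES = ("Con", "Mix", "NF")

#: Forest indicator used by the movement-rate models: Con/Mix -> 1, NF -> 0.
FOREST_CLASSES = frozenset({"Con", "Mix"})


# ---------------------------------------------------------------------------
# GridRaster
# ---------------------------------------------------------------------------

@dataclass
class GridRaster:
    """A planar-gridded field (vegetation height, depth-to-water, landcover).

    Parameters
    ----------
    origin : tuple of float
        (x, y) of the lower-left corner in metres.
    cell_size : float
        Cell edge length in metres (> 0).
    values : ndarray of shape (n_rows, n_cols)
        Row 0 is the northernmost row. ``float`` for continuous fields,
        integer codes for categorical ones.
    nodata : float
        Sentinel for missing cells.
    units : str
        Declares what the cell values mean (``"m"``, ``"class"``,
        ``"km/km2"``).
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0
    units: str = "m"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size,
                y0 + self.n_rows * self.cell_size)

    def cell_index(self, x, y):
        """Row/col of the cell containing (x, y); floor convention.

        Points exactly on the top/right edge are clamped into the grid so
        that the extent is closed.
        """
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        # row 0 is the top row
        row_from_bottom = np.floor((np.asarray(y) - y0) / self.cell_size)
        row = (self.n_rows - 1 - row_from_bottom).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row, col

    def cell_center(self, row, col):
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 + (self.n_rows - np.asarray(row) - 0.5) * self.cell_size
        return x, y

    def value_at(self, x, y):
        row, col = self.cell_index(x, y)
        return self.values[row, col]

    # -- Esri ASCII grid IO --------------------------------------------------

    def write_ascii(self, path) -> None:
        """Write as an Esri ASCII grid (plain text)."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.n_cols}\n")
            fh.write(f"nrows {self.n_rows}\n")
            fh.write(f"xllcorner {self.origin[0]:.6f}\n")
            fh.write(f"yllcorner {self.origin[1]:.6f}\n")
            fh.write(f"cellsize {self.cell_size:.6f}\n")
            fh.write(f"NODATA_value {self.nodata}\n")
            np.savetxt(fh, self.values, fmt="%.6g")

    @classmethod
    def read_ascii(cls, path, units: str = "m") -> "GridRaster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = values.reshape(int(header["nrows"]), int(header["ncols"]))
        return cls(origin=(header["xllcorner"], header["yllcorner"]),
                   cell_size=header["cellsize"], values=values,
                   nodata=header.get("nodata_value", -9999.0), units=units)


# ---------------------------------------------------------------------------
# Decay transforms
# ---------------------------------------------------------------------------

def edist_transform(distance):
    """eDist = 1 - exp(-0.002 * distance[m]); in [0, 1), 0 on the line.

    Saturates beyond ~2 km, bounding the influence of a seismic line on a
    step endpoint to that scale.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return -np.expm1(-EDIST_RATE * d)


def ewam_transform(depth):
    """eWAM = 1 - exp(-1.55 * depth[m]); in [0, 1), 0 at saturated soil.

    Saturates beyond ~3 m depth-to-water, the rooting depth of boreal
    vegetation.
    """
    w = np.asarray(depth, dtype=float)
    if np.any(w < 0):
        raise ValueError("depth must be >= 0")
    return -np.expm1(-EWAM_RATE * w)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_lines(lines, target_length: float = 100.0) -> pd.DataFrame:
    """Partition polylines into ~`target_length` m segments.

    Each polyline is cut into exact ``target_length`` pieces; a terminal
    remainder shorter than half the target is folded into the final piece
    (so lengths are in [target/2, 1.5*target] except for whole lines
    shorter than that), otherwise it stands alone. Total length is
    conserved.

    Returns a DataFrame with columns ``segment_id``, ``line_id``,
    ``geometry`` (shapely LineString) and ``length``.
    """
    records = []
    seg_id = 0
    for line_id, line in enumerate(lines):
        if line.length == 0:
            log.warning("skipping zero-length polyline %d", line_id)
            continue
        total = line.length
        n_full = int(total // target_length)
        remainder = total - n_full * target_length
        # cut positions along the line
        if n_full == 0:
            bounds = [0.0, total]
        elif remainder < 1e-9:
            bounds = [i * target_length for i in range(n_full + 1)]
        elif remainder < target_length / 2:
            # fold the short remainder into the final piece
            bounds = [i * target_length for i in range(n_full)] + [total]
        else:
            bounds = [i * target_length for i in range(n_full + 1)] + [total]
        for a, b in zip(bounds[:-1], bounds[1:]):
            geom = substring(line, a, b)
            records.append((seg_id, line_id, geom, b - a))
            seg_id += 1
    return pd.DataFrame(records,
                        columns=["segment_id", "line_id", "geometry", "length"])


# ---------------------------------------------------------------------------
# Least-cost vegetation height
# ---------------------------------------------------------------------------

def least_cost_veght(segment: LineString, veght_raster: GridRaster,
                     corridor_halfwidth: float = 5.0) -> float:
    """Mean vegetation height along the lowest-vegetation path of a segment.

    Restricted to raster cells within ``corridor_halfwidth`` of the segment,
    finds the 8-connected path between the cells containing the segment's
    endpoints that minimises cumulative cell height (with an epsilon * path
    length term to break ties toward shorter paths), and returns the mean
    height of the cells on that path. This follows game trails: where a low
    lane runs along the line, the returned mean reflects the lane, not the
    regrown flanks.
    """
    eps = 1e-6  # m^-1: tie-break toward shorter paths
    r = veght_raster
    # corridor cell mask
    buf = segment.buffer(corridor_halfwidth)
    x_min, y_min, x_max, y_max = buf.bounds
    r0, c1 = r.cell_index(x_min, y_max)
    r1, c0 = r.cell_index(x_max, y_min)
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c1, c0 + 1),
                             indexing="ij")
    cx, cy = r.cell_center(rows, cols)
    centers = shapely.points(np.c_[cx.ravel(), cy.ravel()])
    within = shapely.distance(centers, segment) <= corridor_halfwidth
    corridor = set(zip(rows.ravel()[within].tolist(),
                       cols.ravel()[within].tolist()))
    # the cells the segment itself crosses form a connected backbone even
    # when the halfwidth is below the cell size
    n_samp = max(2, int(segment.length / (r.cell_size / 2)) + 1)
    ts = np.linspace(0, 1, n_samp)
    sp = [segment.interpolate(t, normalized=True) for t in ts]
    br, bc = r.cell_index(np.array([p.x for p in sp]),
                          np.array([p.y for p in sp]))
    corridor.update(zip(br.tolist(), bc.tolist()))

    p0 = segment.coords[0]
    p1 = segment.coords[-1]
    start = tuple(int(v) for v in r.cell_index(p0[0], p0[1]))
    goal = tuple(int(v) for v in r.cell_index(p1[0], p1[1]))
    corridor.add(start)
    corridor.add(goal)
    for cell in (start, goal):
        if r.values[cell] == r.nodata:
            raise ValueError(
                f"segment endpoint cell {cell} is nodata in veght raster")

    def h(cell):
        v = r.values[cell]
        return math.inf if v == r.nodata else float(v)

    # Dijkstra over corridor cells; node cost = cell height, edge adds the
    # destination's height plus eps * centre-to-centre distance.
    dist = {start: h(start)}
    prev: dict[tuple[int, int], tuple[int, int]] = {}
    pq = [(dist[start], start)]
    seen = set()
    while pq:
        d, cell = heapq.heappop(pq)
        if cell in seen:
            continue
        seen.add(cell)
        if cell == goal:
            break
        cr, cc = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nb = (cr + dr, cc + dc)
                if nb not in corridor or nb in seen:
                    continue
                step = r.cell_size * math.hypot(dr, dc)
                nd = d + h(nb) + eps * step
                if nd < dist.get(nb, math.inf):
                    dist[nb] = nd
                    prev[nb] = cell
                    heapq.heappush(pq, (nd, nb))
    if goal not in dist:
        raise ValueError("no corridor path between segment endpoints")
    # walk the path back and average cell heights
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    return float(np.mean([h(c) for c in path]))


def corridor_mean_veght(segment: LineString, veght_raster: GridRaster,
                        corridor_halfwidth: float = 5.0) -> float:
    """Plain mean height over corridor cells (the non-least-cost baseline)."""
    r = veght_raster
    buf = segment.buffer(corridor_halfwidth)
    x_min, y_min, x_max, y_max = buf.bounds
    r0, c1 = r.cell_index(x_min, y_max)
    r1, c0 = r.cell_index(x_max, y_min)
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c1, c0 + 1),
                             indexing="ij")
    cx, cy = r.cell_center(rows, cols)
    centers = shapely.points(np.c_[cx.ravel(), cy.ravel()])
    within = shapely.distance(centers, segment) <= corridor_halfwidth
    cells = set(zip(rows.ravel()[within].tolist(),
                    cols.ravel()[within].tolist()))
    n_samp = max(2, int(segment.length / (r.cell_size / 2)) + 1)
    sp = [segment.interpolate(t, normalized=True)
          for t in np.linspace(0, 1, n_samp)]
    br, bc = r.cell_index(np.array([p.x for p in sp]),
                          np.array([p.y for p in sp]))
    cells.update(zip(br.tolist(), bc.tolist()))
    vals = np.array([r.values[c] for c in cells])
    vals = vals[vals != r.nodata]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Line density
# ---------------------------------------------------------------------------

def line_density(lines, extent, window_radius: float = 1000.0,
                 cell_size: float = 30.0) -> GridRaster:
    """Line density (km/km^2) in a circular moving window.

    Each cell's value is the total line length inside the window centred on
    the cell, divided by the window area. ``extent`` is
    (x_min, y_min, x_max, y_max).
    """
    x_min, y_min, x_max, y_max = extent
    n_cols = int(math.ceil((x_max - x_min) / cell_size))
    n_rows = int(math.ceil((y_max - y_min) / cell_size))
    values = np.zeros((n_rows, n_cols))
    geoms = [ln for ln in lines if ln.length > 0]
    window_area_km2 = math.pi * (window_radius / 1000.0) ** 2
    if geoms:
        tree = STRtree(geoms)
        for row in range(n_rows):
            for col in range(n_cols):
                cx = x_min + (col + 0.5) * cell_size
                cy = y_min + (n_rows - row - 0.5) * cell_size
                window = Point(cx, cy).buffer(window_radius, quad_segs=32)
                total_m = 0.0
                for idx in tree.query(window):
                    inter = geoms[idx].intersection(window)
                    total_m += inter.length
                values[row, col] = (total_m / 1000.0) / window_area_km2
    return GridRaster(origin=(x_min, y_min), cell_size=cell_size,
                      values=values, units="km/km2")


# ---------------------------------------------------------------------------
# Majority landcover
# ---------------------------------------------------------------------------

def majority_landcover(segment: LineString, landcover_raster: GridRaster,
                       classes=LANDCOVER_CLASSES) -> str:
    """Class whose cells intersect the greatest length of the segment.

    Exact length-by-class: the segment is intersected with each grid cell
    it crosses. Ties break deterministically to the first class in
    ``classes`` order (and are logged).
    """
    r = landcover_raster
    x_min, y_min, x_max, y_max = segment.bounds
    r0, c1 = r.cell_index(x_min, y_max)
    r1, c0 = r.cell_index(x_max, y_min)
    length_by_class: dict[int, float] = {}
    x0, y0 = r.origin
    for row in range(r0, r1 + 1):
        for col in range(c1, c0 + 1):
            cell = box(x0 + col * r.cell_size,
                       y0 + (r.n_rows - row - 1) * r.cell_size,
                       x0 + (col + 1) * r.cell_size,
                       y0 + (r.n_rows - row) * r.cell_size)
            ln = segment.intersection(cell).length
            if ln > 0:
                code = int(r.values[row, col])
                if code != r.nodata:
                    length_by_class[code] = length_by_class.get(code, 0.0) + ln
    if not length_by_class:
        raise ValueError("segment intersects only nodata landcover cells")
    best = max(length_by_class.values())
    winners = [code for code, ln in length_by_class.items()
               if abs(ln - best) < 1e-9]
    # code i encodes classes[i]
    winners_named = sorted((classes[c] for c in winners),
                           key=lambda name: classes.index(name))
    if len(winners_named) > 1:
        log.info("landcover tie on segment: %s -> %s",
                 winners_named, winners_named[0])
    return winners_named[0]


def reflect_into(v, lo: float, hi: float):
    """Reflect coordinates at [lo, hi] boundaries (repeated until inside).

    The boundary treatment for simulated movement and for available-step
    endpoints alike: reflection rather than truncation avoids piling points
    on the edge and the selection artifacts that truncation induces.
    """
    v = np.asarray(v, dtype=float).copy()
    for _ in range(10):
        below, above = v < lo, v > hi
        if not (below.any() or above.any()):
            break
        v[below] = 2 * lo - v[below]
        v[above] = 2 * hi - v[above]
    return np.clip(v, lo, hi)


# ---------------------------------------------------------------------------
# Nearest-segment queries
# ---------------------------------------------------------------------------

class SegmentIndex:
    """Spatial index over attributed segments for nearest queries.

    Wraps an STRtree; ``nearest`` returns (segment row positions, distances)
    and must agree exactly with a brute-force scan.
    """

    def __init__(self, segments: pd.DataFrame):
        if len(segments) == 0:
            raise ValueError("need at least one segment")
        self.segments = segments.reset_index(drop=True)
        self._geoms = np.asarray(self.segments["geometry"].tolist(),
                                 dtype=object)
        self._tree = STRtree(self._geoms)
        # attribute arrays cached for fast covariate lookup
        self.attrs = {
            col: self.segments[col].to_numpy()
            for col in ("segment_id", "veght", "ewam", "density", "landcover")
            if col in self.segments
        }

    def nearest(self, x, y):
        """Nearest segment row position and Euclidean distance per point."""
        pts = shapely.points(np.c_[np.atleast_1d(x).astype(float),
                                   np.atleast_1d(y).astype(float)])
        idx = self._tree.nearest(pts)
        dist = shapely.distance(pts, self._geoms[idx])
        return np.asarray(idx), np.asarray(dist)


def nearest_segment(x, y, segments: pd.DataFrame):
    """(segment_id, distance m) of the closest segment to a point.

    Convenience wrapper over :class:`SegmentIndex` for scalar queries.
    """
    index = SegmentIndex(segments)
    idx, dist = index.nearest(x, y)
    seg_ids = index.segments["segment_id"].to_numpy()[idx]
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return int(seg_ids[0]), float(dist[0])
    return seg_ids, dist


# ---------------------------------------------------------------------------
# Full attribution
# ---------------------------------------------------------------------------

def attribute_segments(lines, veght_raster: GridRaster,
                       wam_raster: GridRaster,
                       landcover_raster: GridRaster,
                       density_raster: GridRaster | None = None,
                       target_length: float = 100.0,
                       corridor_halfwidth: float = 5.0) -> pd.DataFrame:
    """Segment a network and attach Veght, eWAM, landcover and Density.

    Returns the segment table with columns ``segment_id``, ``line_id``,
    ``geometry``, ``length``, ``veght``, ``wam``, ``ewam``, ``landcover``,
    ``density``.
    """
    segs = segment_lines(lines, target_length=target_length)
    if density_raster is None:
        ext = veght_raster.extent
        density_raster = line_density(lines, ext,
                                      cell_size=veght_raster.cell_size)
    veght, wam, dens, land = [], [], [], []
    for _, row in segs.iterrows():
        geom = row["geometry"]
        mid = geom.interpolate(0.5, normalized=True)
        veght.append(least_cost_veght(geom, veght_raster,
                                      corridor_halfwidth=corridor_halfwidth))
        wam.append(float(wam_raster.value_at(mid.x, mid.y)))
        dens.append(float(density_raster.value_at(mid.x, mid.y)))
        land.append(majority_landcover(geom, landcover_raster))
    segs["veght"] = veght
    segs["wam"] = wam
    segs["ewam"] = ewam_transform(np.maximum(segs["wam"].to_numpy(), 0.0))
    segs["landcover"] = land
    segs["density"] = dens
    return segs
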